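# Methods

## Problem and model

Surface EMG during aggressive actions is markedly non-Gaussian and
nonlinear, while second-order tools (the power spectrum) are blind to the
phase structure that carries this information.  The pipeline therefore
classifies episodes on a third-order statistic.  For a zero-mean stationary
signal x(k) the third-order cumulant is

    C3(n1, n2) = E[x(k) x(k+n1) x(k+n2)],

identically zero for any Gaussian process and symmetric under
C3(n1,n2) = C3(n2,n1) = C3(-n1, n2-n1) = C3(n1-n2, -n2).  Its 2-D Fourier
transform is the bispectrum B(w1, w2), equivalently the averaged Fourier
triple product <X(w1) X(w2) X*(w1+w2)>.  Three spectral lines at f1, f2 and
f1+f2 whose phases satisfy phi3 = phi1 + phi2 (quadratic phase coupling,
QPC) put a peak at (f1, f2); with independent phases the ensemble average
cancels and the bispectrum is flat.  Everything non-redundant lives in the
principal triangle 0 <= w2 <= w1, w1 + w2 <= Nyquist.  The per-episode
feature is the scalar

    D = sum over the principal domain, w1 != w2, of |B(w1, w2)|,

fed to an extreme learning machine (ELM): a single-hidden-layer network
whose input weights and biases are random and fixed, with output weights
solved in closed form as beta = pinv(H) Y (minimum-norm least squares on
the one-hot targets).

## Estimators

* **Indirect**: sample-cumulant lattice on |n1|,|n2| <= max_lag, tapered by
  a separable peak-normalized 2-D Hann lag window, zero-padded and 2-D
  FFT'd.  Defaults: biased estimator (divide by N), max_lag = window
  support = round(0.05 s * fs) = 50 at fs = 1000 Hz, nfft = 128.  Each lag
  pair's triple product is evaluated with its index offsets sorted, so all
  six symmetry images of a lag pair sum the identical float sequence and
  the lag symmetries hold bitwise for both the biased and unbiased
  estimators.
* **Direct**: split into segments (default 256 samples, 50% overlap),
  mean-center and 1-D-Hann-taper each, FFT, accumulate
  X(w1) X(w2) X*(w1+w2) with (w1+w2) wrapped modulo nfft, and average.
  Default nfft = 256 (the FFT cannot be shorter than a segment, so the
  direct method does not share the indirect method's nfft = 128 default).
* Grids are stored over [0, fs) on both axes; the principal domain is
  evaluated on bin indices (j <= i, i + j <= nfft/2, boundaries included).
  Episodes are always mean-centered before any cumulant or FFT.
* No bicoherence normalization is applied: D sums raw magnitudes, so
  D(a*x) = a^3 D(x).  A per-episode variance-normalization flag exists for
  amplitude-confounded data (default off).  The w1 != w2 exclusion is read
  as excluding exactly the diagonal cells of the discrete grid.

The pipeline's default estimator is the direct one (an order of magnitude
cheaper per 10 s episode at these settings); both produce the same triad
localization (checked by a cross-estimator argmax test).  QPC-localization
experiments run both estimators at nfft = 256: at nfft = 128 the default
triad (40, 90) Hz falls about half a bin from the nearest line, and
leakage can move the argmax to the neighboring cell — a grid-resolution
artifact rather than an estimator property.

## Synthetic study conditions

The generator emulates the structure of 8-channel, ~10,000-sample, 10 s
action recordings at a nominal 1 kHz (the recorded corpus states samples
and duration; 1 kHz is the implied rate).  Each episode is a tone stack:
unit-amplitude lines at f1 and f2, a triad line at f1+f2 with amplitude
`coupling_amplitude` (default 1), an incoherent line at f3 with amplitude
`uncoupled_amplitude` (default 0.5), plus white Gaussian noise
(sd 0.1).  The aggressive class uses a low-frequency triad (40, 90 Hz,
mirroring the observation that aggressive coupling concentrates at low
frequencies); the normal class places its — uncoupled — tones above 100 Hz
(120, 180 Hz).  Channels beyond the first repeat the construction with
independent phases; no cross-channel coupling is modeled.

**Phase coherence.**  Phases are redrawn independently every
`phase_coherence_samples` samples (default 250, i.e. a 0.25 s coherence
time), with the triad lock phi3 = phi1 + phi2 holding exactly within each
block of the coupled class.  This is deliberate: with a single phase draw
per episode the offset phi3 - phi1 - phi2 of an *uncoupled* triad is
constant in time, every analysis segment sees the same triple-product
phase, and no estimator that averages within one realization can
distinguish coupled from uncoupled — the expectation in
B = <X X X*> is an ensemble average, and a finite coherence time is what
makes segment averaging realize it.  Numerically, the single-draw
construction gives D(coupled) ≈ D(uncoupled) (≈680,000 vs ≈678,000 at
default settings), while the piecewise-coherent one separates the classes
by more than a factor of three with non-overlapping ranges.

What the generator does **not** emulate: motor-unit action-potential
trains, amplitude nonstationarity (bursts), movement artifacts, colored
noise, or cross-channel correlation.  Passing tests therefore demonstrate
that the pipeline detects and exploits quadratic phase coupling under
controlled conditions — not that real EMG recordings are this separable.

## Classifier

Study configuration: 1 input node (D), 40 hidden nodes, 2 output nodes,
logistic sigmoid activation.  Weights and biases are uniform on [-1, 1]
(the distribution is otherwise unconstrained); features are affinely
scaled to [-1, 1] using training extremes because D spans orders of
magnitude; targets are one-hot in alphabetical class order
(aggressive, normal); prediction is argmax with ties to the first class.
The pseudoinverse uses a rank-revealing SVD with default tolerance; an
optional ridge term (default 0) is available for numerically singular
hidden matrices.  The train/test split is random, 50%-50%, stratified by
class (stratification stabilizes small corpora; the original split method
is unspecified beyond "random").

Default `channel_mode="per_channel"` treats each channel-episode as one
classification sample with the single feature D, reconciling 8-channel
recordings with the 1-input-node network; `"summed"` instead sums D over a
recording's channels into one sample.

## Numerical and design notes

* Biased cumulant lattices are used for the indirect estimator because
  their symmetries are exact; unbiased lattices divide by the count of
  valid terms per lag.
* The direct estimator warns (but proceeds) below 2 segments and refuses
  an episode shorter than one segment.
* The reader drops rows containing non-finite values and counts them on
  the returned episodes; ragged or non-numeric rows are hard errors naming
  the first offending line.  The writer's default `%.17g` format makes
  write-then-read an exact identity on doubles.
* Scale of the replicated experiments: the classification study uses 100
  episodes per class and 20 replicates; QPC contrast uses 50 matched seed
  pairs; Gaussian-decay checks use 20 seeds at N = 25,000 and 100,000.
  These sizes give stable Monte-Carlo estimates (the observed decay ratio
  is within 5% of the theoretical 2.0) at desk-scale runtimes.
* All randomness flows through explicit integer seeds (numpy Generator /
  SeedSequence); every generator, split and ELM initialization is a pure
  function of its seed.

## Known limitations

* D is amplitude-cubed sensitive; on real data with variable gain the
  variance-normalization flag (or bicoherence, out of scope) would be
  needed.
* Localization tests assume the triad lies inside the principal triangle
  and away from the diagonal; triads with f1 = f2 (self-coupling) are
  excluded by construction.
* The ELM decision rule, weight distribution and input scaling are design
  choices where the underlying method leaves them open; they are fixed and
  documented rather than tuned.
* Real-data accuracy depends on the external recorded corpus and is
  reported without any asserted threshold.
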