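# hosemg

Higher-order-spectra analysis of surface electromyography (EMG) for
separating **aggressive** from **normal** physical actions.

EMG episodes from aggressive movements are strongly non-Gaussian: their
spectral components exhibit **quadratic phase coupling** (QPC) — triads of
lines at f1, f2 and f1+f2 whose phases satisfy φ3 = φ1 + φ2.  The power
spectrum cannot see this (it is phase-blind), but the **bispectrum**

    B(ω1, ω2) = ⟨X(ω1) X(ω2) X*(ω1+ω2)⟩,

the 2-D Fourier transform of the third-order cumulant
C3(n1,n2) = E[x(k) x(k+n1) x(k+n2)], shows a peak at (f1, f2) exactly when
the triad is phase-locked.  Each episode is reduced to the scalar feature

    D = Σ |B(ω1, ω2)|  over the principal triangle 0 ≤ ω2 ≤ ω1, ω1+ω2 ≤ π,  ω1 ≠ ω2,

and D is classified by an **extreme learning machine** (ELM): a
single-hidden-layer network with random fixed input weights whose output
weights are solved analytically, β̂ = H⁺Y (Moore-Penrose minimum-norm
least squares on the hidden activations H and one-hot targets Y).

The package provides:

* `hosemg.hos` — third-order cumulants (biased/unbiased, exact lag
  symmetries), indirect (cumulant + 2-D Hann lag window + FFT) and direct
  (segment-averaged triple product) bispectrum estimators, principal
  domain, the QPC quantity D, and a matching power spectrum;
* `hosemg.synthetic` — a deterministic generator of labeled 1 kHz, 10 s
  episodes with controlled QPC (phase-locked triads for the aggressive
  class, uncoupled for the normal class);
* `hosemg.io_uci` — reader/writer for the plain-text multi-column dialect
  of the public "EMG physical action" archive (8 channels per recording,
  labels from the Normal/Aggressive directory layout);
* `hosemg.elm` — the ELM classifier with serialization;
* `hosemg.pipeline` + a `hosemg` CLI — the end-to-end study;
* `analysis/` — numbered drivers that narrate the study and write tables
  under `results/`.

## Worked example

```bash
python analysis/02_extract_features.py
python analysis/03_classify.py
```

prints (abridged):

```
extracted D for 100 episodes (direct estimator, nfft=256)
                mean      std       min       max
label
aggressive  759486.0  11386.0  733503.0  788476.0
normal      166143.0  36095.0  105989.0  258115.0

class gap (min aggressive D - max normal D): 475388

train accuracy   : 1.0000
test accuracy    : 1.0000
confusion (truth -> predicted):
  aggressive  : {'aggressive': 25, 'normal': 0}
  normal      : {'aggressive': 0, 'normal': 25}

20-replicate study: median test accuracy 100.00% (min 100.00%)
```

The phase-locked triads of the aggressive class push their summed
bispectral magnitude D more than a factor of three above the uncoupled
normal class with non-overlapping ranges, so the 1-input / 40-hidden /
2-output sigmoid ELM separates the classes perfectly on the synthetic
corpus.  `analysis/04_diagnostics.py` confirms the machinery: Gaussian
noise drives max|C3| down as 1/√N (observed ratio 2.09 vs theoretical 2.0
when N is quadrupled), both estimators localize the triad at (f1, f2) in
10/10 seeds, and shuffling labels collapses accuracy to 0.48 (chance).

The same pipeline runs on the real archive via the CLI:

```bash
hosemg synth --out corpus/ --n-per-class 10 --seed 7   # or a downloaded UCI tree
hosemg features --in corpus/ --out features.tsv
hosemg run --config cfg.yaml --report-out report.json
```

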