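"""Higher-order-spectra engine: third-order cumulants and the bispectrum.

For a zero-mean stationary discrete signal x(k) the third-order cumulant is

    C3(n1, n2) = E[ x(k) x(k+n1) x(k+n2) ],

which is identically zero for Gaussian processes and obeys the lag
symmetries C3(n1,n2) = C3(n2,n1) = C3(-n1, n2-n1) = C3(n1-n2, -n2).  The
bispectrum is its 2-D Fourier transform,

    B(w1, w2) = sum_{n1,n2} C3(n1,n2) W(n1,n2) e^{-j(w1 n1 + w2 n2)},

estimated here two ways: the *indirect* route above (sample cumulant lattice
tapered by a separable 2-D Hann window W, then FFT) and the *direct* route
B(w1,w2) = <X(w1) X(w2) X*(w1+w2)> averaged over tapered segments.  A
quadratic phase coupling (three lines at f1, f2, f1+f2 with phases summing
coherently) shows up as a bispectral peak at (f1, f2); the scalar feature

    D = sum |B(w1, w2)|  over the principal domain, w1 != w2,

quantifies the total coupling (and non-Gaussianity) of an episode.

Conventions fixed here: frequency grids live on [0, fs) with (w1+w2) taken
modulo the FFT length; the principal domain is the triangle
0 <= w2 <= w1, w1 + w2 <= Nyquist; signals are mean-centered before any
cumulant or FFT; magnitudes are raw (no bicoherence normalization), so
D(a*x) = a^3 D(x).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from hosemg.io_uci import Episode

log = logging.getLogger(__name__)

ESTIMATORS = ("biased", "unbiased")


@dataclass
class CumulantLattice:
    """Sample third-order cumulant on the square lag grid |n1|,|n2| <= max_lag.

    ``values[i, j]`` holds C3(n1, n2) with n1 = lags[i], n2 = lags[j].
    """

    values: np.ndarray
    max_lag: int
    estimator: str = "biased"
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        side = 2 * self.max_lag + 1
        if self.values.shape != (side, side):
            raise ValueError(
                f"lattice shape {self.values.shape} does not match "
                f"max_lag={self.max_lag}"
            )
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")

    @property
    def lags(self) -> np.ndarray:
        return np.arange(-self.max_lag, self.max_lag + 1)


@dataclass
class BispectrumGrid:
    """Complex bispectrum on a regular nfft x nfft bifrequency grid.

    freq_axis covers [0, fs); ``values[i, j]`` is B(w1=freq_axis[i],
    w2=freq_axis[j]).
    """

    values: np.ndarray
    freq_axis: np.ndarray
    sampling_rate: float
    method: str
    window_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        n = self.freq_axis.size
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match freq_axis")
        if not np.all(np.isfinite(self.values.view(float))):
            raise ValueError("bispectrum grid contains non-finite values")

    @property
    def nfft(self) -> int:
        return self.freq_axis.size


@dataclass
class QpcQuantity:
    """Summed bispectral magnitude D over the off-diagonal principal domain."""

    D: float
    n_cells: int
    method: str


def _center(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x - x.mean()


def _lag_product_sum(xc: np.ndarray, n1: int, n2: int) -> tuple[float, int]:
    """Sum of x(k) x(k+n1) x(k+n2) over all valid k, plus the term count.

    The three offsets {0, n1, n2} are sorted before multiplying, so every
    member of a symmetry orbit sums the identical float sequence and the
    lag symmetries hold bitwise for both estimators.
    """
    o0, o1, o2 = sorted((0, n1, n2))
    span = o2 - o0
    m = xc.size - span
    if m <= 0:
        return 0.0, 0
    p = xc[o0 - o0 : o0 - o0 + m] * xc[o1 - o0 : o1 - o0 + m]
    p = p * xc[o2 - o0 : o2 - o0 + m]
    return float(np.sum(p)), m


def third_order_cumulant(
    x: Episode | np.ndarray, max_lag: int, estimator: str = "biased"
) -> CumulantLattice:
    """Sample third-order cumulant lattice of a mean-centered signal.

    The biased estimator divides every lag's sum by N (guaranteeing the lag
    symmetries and a positive-semidefinite-style shrinkage toward zero at
    large lags); the unbiased one divides by the number of valid terms.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if isinstance(x, Episode):
        samples, fs = x.samples, x.sampling_rate
    else:
        samples, fs = np.asarray(x, dtype=float), 1000.0
    if samples.size == 0:
        raise ValueError("empty signal")
    if samples.size <= 2 * max_lag:
        raise ValueError(
            f"signal length {samples.size} too short for max_lag={max_lag} "
            f"(need > {2 * max_lag})"
        )
    xc = _center(samples)
    n = xc.size
    side = 2 * max_lag + 1
    values = np.empty((side, side))
    for i, n1 in enumerate(range(-max_lag, max_lag + 1)):
        for j, n2 in enumerate(range(-max_lag, n1 + 1)):
            s, m = _lag_product_sum(xc, n1, n2)
            c = s / n if estimator == "biased" else (s / m if m else 0.0)
            values[i, j] = c
            values[j, i] = c  # C3(n1,n2) = C3(n2,n1)
    return CumulantLattice(
        values=values, max_lag=max_lag, estimator=estimator, sampling_rate=fs
    )


def hanning_2d(max_lag: int) -> np.ndarray:
    """Separable 2-D Hann lag window W(n1,n2) = w(n1) w(n2).

    ``w`` is peak-normalized (w(0) = 1), spans lags |n| <= max_lag and
    vanishes at the support edge.  At fs = 1000 Hz the 0.05 s window of the
    study corresponds to max_lag = 50.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    w = hann(2 * max_lag + 1, sym=True)
    return np.outer(w, w)


def bispectrum_indirect(
    c3: CumulantLattice, window: np.ndarray | None = None, nfft: int = 128
) -> BispectrumGrid:
    """Indirect bispectrum: 2-D DFT of the windowed cumulant lattice.

    The lattice (elementwise-tapered by ``window``, default the 2-D Hann of
    matching support) is placed on the nfft x nfft grid with negative lags
    wrapped, then transformed; the grid covers [0, fs) on both axes.
    """
    side = 2 * c3.max_lag + 1
    if window is None:
        window = hanning_2d(max(c3.max_lag, 1))
    window = np.asarray(window, dtype=float)
    if window.shape[0] > side or window.shape[1] > side:
        raise ValueError(
            f"window {window.shape} larger than lattice support {side}x{side}"
        )
    if nfft < side:
        raise ValueError(f"nfft={nfft} smaller than lattice width {side}")
    tapered = np.zeros((side, side))
    # center the (possibly smaller) window on lag (0, 0)
    wl = (window.shape[0] - 1) // 2
    lo, hi = c3.max_lag - wl, c3.max_lag + wl + 1
    tapered[lo:hi, lo:hi] = c3.values[lo:hi, lo:hi] * window
    padded = np.zeros((nfft, nfft))
    lags = np.arange(-c3.max_lag, c3.max_lag + 1)
    idx = np.mod(lags, nfft)
    padded[np.ix_(idx, idx)] = tapered
    values = np.fft.fft2(padded)
    freq = np.arange(nfft) * c3.sampling_rate / nfft
    return BispectrumGrid(
        values=values,
        freq_axis=freq,
        sampling_rate=c3.sampling_rate,
        method="indirect",
        window_tag=f"hann2d({window.shape[0]})",
    )


def _segments(x: np.ndarray, segment_length: int, overlap_fraction: float):
    step = max(1, int(round(segment_length * (1.0 - overlap_fraction))))
    starts = range(0, x.size - segment_length + 1, step)
    return [x[s : s + segment_length] for s in starts]


def bispectrum_direct(
    x: Episode,
    segment_length: int = 256,
    nfft: int = 256,
    overlap_fraction: float = 0.5,
) -> BispectrumGrid:
    """Direct bispectrum: segment-averaged FFT triple products.

    Per segment: mean-center, taper with a 1-D Hann, FFT to nfft bins, and
    accumulate X(w1) X(w2) X*(w1+w2) with (w1+w2) wrapped modulo nfft; the
    average over segments estimates the expectation.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if nfft < segment_length:
        raise ValueError(f"nfft={nfft} must be >= segment_length={segment_length}")
    if len(x) < segment_length:
        raise ValueError(
            f"episode length {len(x)} shorter than segment_length={segment_length}"
        )
    segs = _segments(x.samples, segment_length, overlap_fraction)
    if len(segs) < 2:
        log.warning(
            "bispectrum_direct: only %d segment(s); variance of the "
            "estimate will be high",
            len(segs),
        )
    taper = hann(segment_length, sym=False)
    idx = np.add.outer(np.arange(nfft), np.arange(nfft)) % nfft
    acc = np.zeros((nfft, nfft), dtype=complex)
    buf = np.empty((nfft, nfft), dtype=complex)
    for seg in segs:
        X = np.fft.fft((seg - seg.mean()) * taper, n=nfft)
        np.multiply(X[:, None], X[None, :], out=buf)
        buf *= np.conj(X)[idx]
        acc += buf
    values = acc / len(segs)
    freq = np.arange(nfft) * x.sampling_rate / nfft
    return BispectrumGrid(
        values=values,
        freq_axis=freq,
        sampling_rate=x.sampling_rate,
        method="direct",
        window_tag=f"hann1d({segment_length})",
    )


def principal_domain_mask(nfft: int, sampling_rate: float = 1000.0) -> np.ndarray:
    """Boolean mask of the non-redundant triangle 0 <= w2 <= w1, w1+w2 <= pi.

    pi corresponds to Nyquist (= nfft/2 bins on the [0, fs) grid); all
    boundaries are included.  For large nfft the triangle covers about
    nfft^2/16 cells.
    """
    if nfft < 2:
        raise ValueError("nfft must be >= 2")
    i = np.arange(nfft)
    w1 = i[:, None]
    w2 = i[None, :]
    return (w2 <= w1) & (w1 + w2 <= nfft // 2)


def qpc_quantity(B: BispectrumGrid) -> QpcQuantity:
    """QPC feature D: summed |B| over the principal domain, diagonal excluded.

    The w1 = w2 diagonal is excluded exactly (discrete cells with equal
    indices); the remaining principal-domain magnitudes are summed raw, so
    D scales with the cube of signal amplitude.
    """
    if not np.all(np.isfinite(B.values.view(float))):
        raise ValueError("bispectrum grid contains non-finite values")
    mask = principal_domain_mask(B.nfft, B.sampling_rate)
    off_diag = ~np.eye(B.nfft, dtype=bool)
    cells = mask & off_diag
    D = float(np.abs(B.values[cells]).sum())
    return QpcQuantity(D=D, n_cells=int(cells.sum()), method=B.method)


def power_spectrum(
    x: Episode, segment_length: int = 256, nfft: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Segment-averaged periodogram with the direct estimator's conventions.

    Returns (freq_axis on [0, fs), power density).  Normalized so that the
    density integrated over [0, fs) equals the tapered signal's variance
    (single-sided readers should fold the upper half).
    """
    if len(x) < segment_length:
        raise ValueError(
            f"episode length {len(x)} shorter than segment_length={segment_length}"
        )
    if nfft < segment_length:
        raise ValueError("nfft must be >= segment_length")
    segs = _segments(x.samples, segment_length, 0.5)
    taper = hann(segment_length, sym=False)
    scale = (taper**2).sum() * x.sampling_rate
    acc = np.zeros(nfft)
    for seg in segs:
        X = np.fft.fft((seg - seg.mean()) * taper, n=nfft)
        acc += np.abs(X) ** 2
    psd = acc / (len(segs) * scale)
    freq = np.arange(nfft) * x.sampling_rate / nfft
    return freq, psd
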