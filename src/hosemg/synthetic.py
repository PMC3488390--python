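"""Synthetic EMG-like episodes with controlled quadratic phase coupling.

Quadratic phase coupling (QPC) means three spectral lines at f1, f2 and
f1+f2 whose phases satisfy phi3 = phi1 + phi2.  Such a triad produces a
bispectral peak at (f1, f2) while leaving the power spectrum unchanged, so
it is the minimal signal that separates second-order from third-order
analysis.  The generators here build labeled corpora in which "aggressive"
episodes carry a phase-locked triad concentrated at low frequencies and
"normal" episodes carry the same tones with an independent third phase
(no coupling), mirroring the structure the bispectral feature is meant to
detect in real recordings.

These are tone-plus-noise surrogates, not biophysical EMG: there are no
motor-unit action-potential trains, no nonstationarity and the noise is
white Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from hosemg.io_uci import Episode

__all__ = [
    "SyntheticSpec",
    "LabeledEpisodeSet",
    "generate_coupled_episode",
    "generate_uncoupled_episode",
    "generate_corpus",
    "AGGRESSIVE_SPEC",
    "NORMAL_SPEC",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic episode family.

    The base tones at ``f1`` and ``f2`` have unit amplitude; the triad tone
    at ``f1 + f2`` has amplitude ``coupling_amplitude`` and, in the coupled
    generator, phase locked to phi1 + phi2.  An extra tone at ``f3`` with
    amplitude ``uncoupled_amplitude`` and an independent phase is always
    incoherent with the triad.  White Gaussian noise with standard
    deviation ``noise_sd`` is added.  ``seed`` fully determines the output.
    """

    sampling_rate: float = 1000.0
    duration: float = 10.0
    f1: float = 40.0
    f2: float = 90.0
    f3: float = 175.0
    base_amplitude: float = 1.0
    coupling_amplitude: float = 1.0
    uncoupled_amplitude: float = 0.5
    noise_sd: float = 0.1
    n_channels: int = 1
    phase_coherence_samples: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        nyquist = self.sampling_rate / 2.0
        if self.f1 == self.f2:
            raise ValueError("f1 and f2 must differ")
        for name, f in (("f1", self.f1), ("f2", self.f2), ("f3", self.f3)):
            if not 0 < f < nyquist:
                raise ValueError(f"{name}={f} must lie in (0, Nyquist={nyquist})")
        if self.f1 + self.f2 >= nyquist:
            raise ValueError(
                f"triad sum f1+f2={self.f1 + self.f2} must be below "
                f"Nyquist={nyquist}"
            )
        for name, a in (
            ("base_amplitude", self.base_amplitude),
            ("coupling_amplitude", self.coupling_amplitude),
            ("uncoupled_amplitude", self.uncoupled_amplitude),
            ("noise_sd", self.noise_sd),
        ):
            if a < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.phase_coherence_samples < 1:
            raise ValueError("phase_coherence_samples must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))


@dataclass
class LabeledEpisodeSet:
    """Parallel lists of episodes and class labels."""

    episodes: list[Episode]
    labels: list[str]
    action_name: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.episodes:
            raise ValueError("episode set is empty")
        if len(self.episodes) != len(self.labels):
            raise ValueError("episodes and labels must be parallel")

    def __len__(self) -> int:
        return len(self.episodes)


# Default study conditions: the aggressive class puts the triad below 100 Hz
# (f1+f2=130 Hz), the normal class above; amplitudes and noise are matched
# so the power spectra differ only through frequency placement.
AGGRESSIVE_SPEC = SyntheticSpec(f1=40.0, f2=90.0, f3=175.0)
NORMAL_SPEC = SyntheticSpec(f1=120.0, f2=180.0, f3=233.0)


def _tones(spec: SyntheticSpec, rng: np.random.Generator, locked: bool) -> np.ndarray:
    """Piecewise-coherent tone stack.

    Phases are redrawn every ``phase_coherence_samples`` samples (the
    tones' coherence time), realizing the ensemble the bispectrum's
    expectation operator averages over: within each block the triad phase
    is locked (coupled) or independent (uncoupled), and across blocks the
    phases are independent draws.  A strictly stationary single phase draw
    per episode would make coupled and uncoupled episodes bispectrally
    identical — the phase offset phi3 - phi1 - phi2 would be constant in
    time and no amount of segment averaging could cancel it.
    """
    n = spec.n_samples
    t = np.arange(n) / spec.sampling_rate
    x = np.zeros(n)
    for start in range(0, n, spec.phase_coherence_samples):
        sl = slice(start, min(start + spec.phase_coherence_samples, n))
        phi1, phi2, phi3 = rng.uniform(0.0, 2.0 * np.pi, size=3)
        phi_triad = phi1 + phi2 if locked else rng.uniform(0.0, 2.0 * np.pi)
        tt = t[sl]
        x[sl] = (
            spec.base_amplitude * np.cos(2.0 * np.pi * spec.f1 * tt + phi1)
            + spec.base_amplitude * np.cos(2.0 * np.pi * spec.f2 * tt + phi2)
            + spec.coupling_amplitude
            * np.cos(2.0 * np.pi * (spec.f1 + spec.f2) * tt + phi_triad)
            + spec.uncoupled_amplitude * np.cos(2.0 * np.pi * spec.f3 * tt + phi3)
        )
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, size=n)
    return x


def _episode(
    spec: SyntheticSpec, locked: bool, label: str, channel: int,
    recording_id: str = "",
) -> Episode:
    # One independent phase draw per (seed, channel, locked-ness); the
    # channel index enters the stream so channels are independent.
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(channel,))
    )
    x = _tones(spec, rng, locked=locked)
    tag = "coupled" if locked else "uncoupled"
    return Episode(
        samples=x,
        sampling_rate=spec.sampling_rate,
        channel_name=f"ch{channel + 1}",
        action=f"synthetic-{tag}",
        label=label,
        recording_id=recording_id or f"synthetic-{tag}-seed{spec.seed}",
    )


def generate_coupled_episode(spec: SyntheticSpec, channel: int = 0) -> Episode:
    """Episode with a phase-locked triad: phases satisfy phi3 = phi1 + phi2.

    The triad produces a bispectral peak in the cell containing (f1, f2);
    the power spectrum is identical to the uncoupled counterpart.
    """
    return _episode(spec, locked=True, label="aggressive", channel=channel)


def generate_uncoupled_episode(spec: SyntheticSpec, channel: int = 0) -> Episode:
    """Episode with the same tones but an independent phase on f1+f2.

    Serves as the null: same second-order statistics, no quadratic phase
    coupling, hence a flat (sampling-noise-level) bispectrum.
    """
    return _episode(spec, locked=False, label="normal", channel=channel)


def generate_corpus(
    n_per_class: int,
    aggressive_spec: SyntheticSpec = AGGRESSIVE_SPEC,
    normal_spec: SyntheticSpec = NORMAL_SPEC,
    seed: int = 0,
) -> LabeledEpisodeSet:
    """Labeled corpus: n_per_class coupled ("aggressive") + uncoupled
    ("normal") episodes, deterministic under ``seed``.

    Episode seeds are spawned from ``seed`` so corpora with different seeds
    are independent while the same seed reproduces the corpus exactly.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    episodes: list[Episode] = []
    labels: list[str] = []
    # Distinct deterministic per-episode seeds below 2**31.
    rng = np.random.default_rng(seed)
    ep_seeds = rng.integers(0, 2**31 - 1, size=2 * n_per_class)
    for i in range(n_per_class):
        spec_a = replace(aggressive_spec, seed=int(ep_seeds[2 * i]))
        spec_n = replace(normal_spec, seed=int(ep_seeds[2 * i + 1]))
        for ch in range(spec_a.n_channels):
            episodes.append(generate_coupled_episode(spec_a, channel=ch))
            labels.append("aggressive")
        for ch in range(spec_n.n_channels):
            episodes.append(generate_uncoupled_episode(spec_n, channel=ch))
            labels.append("normal")
    return LabeledEpisodeSet(episodes=episodes, labels=labels, action_name="synthetic")
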