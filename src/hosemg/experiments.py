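"""Reusable validation experiments over the synthetic study conditions.

Each function runs one self-contained numerical experiment — cumulant
estimator checks, QPC detection/contrast Monte Carlo, ELM solver checks,
and the end-to-end classification study — and returns plain numbers.  The
analysis drivers, the test suite and the acceptance script all call these
instead of re-implementing the loops.

All randomness is derived from an explicit ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from hosemg.elm import FeatureTable, accuracy, elm_predict, elm_train
from hosemg.hos import (
    bispectrum_direct,
    bispectrum_indirect,
    principal_domain_mask,
    qpc_quantity,
    third_order_cumulant,
)
from hosemg.pipeline import PipelineConfig, extract_features, run_pipeline, split_train_test
from hosemg.synthetic import (
    AGGRESSIVE_SPEC,
    SyntheticSpec,
    generate_corpus,
    generate_coupled_episode,
    generate_uncoupled_episode,
)

__all__ = [
    "third_order_cumulant_reference",
    "cumulant_oracle_max_error",
    "cumulant_symmetry_max_error",
    "gaussian_cumulant_scaling",
    "qpc_detection_rates",
    "qpc_contrast",
    "qpc_contrast_by_amplitude",
    "elm_solver_errors",
    "classification_study",
    "label_shuffle_null",
]


def third_order_cumulant_reference(
    x: np.ndarray, max_lag: int, estimator: str = "biased"
) -> np.ndarray:
    """Brute-force triple-loop C3(n1,n2); the independent oracle.

    Literally sums x(k) x(k+n1) x(k+n2) over every valid k with Python
    loops; O(N * max_lag^2), for validation at small sizes only.
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    n = xc.size
    side = 2 * max_lag + 1
    out = np.zeros((side, side))
    for i, n1 in enumerate(range(-max_lag, max_lag + 1)):
        for j, n2 in enumerate(range(-max_lag, max_lag + 1)):
            total = 0.0
            count = 0
            for k in range(n):
                k1, k2 = k + n1, k + n2
                if 0 <= k1 < n and 0 <= k2 < n:
                    total += xc[k] * xc[k1] * xc[k2]
                    count += 1
            denom = n if estimator == "biased" else max(count, 1)
            out[i, j] = total / denom
    return out


def cumulant_oracle_max_error(
    seed: int = 0,
    n_signals: int = 12,
    lengths: tuple[int, ...] = (9, 16, 33, 64),
    max_lag: int = 4,
) -> dict[str, float]:
    """Max |fast - brute force| over random signals, both estimators."""
    rng = np.random.default_rng(seed)
    worst = {"biased": 0.0, "unbiased": 0.0}
    for length in lengths:
        for _ in range(n_signals):
            x = rng.normal(size=length)
            for est in ("biased", "unbiased"):
                fast = third_order_cumulant(x, max_lag, est).values
                ref = third_order_cumulant_reference(x, max_lag, est)
                worst[est] = max(worst[est], float(np.abs(fast - ref).max()))
    return worst


def cumulant_symmetry_max_error(
    seed: int = 0, n_signals: int = 100, length: int = 200, max_lag: int = 6
) -> float:
    """Max violation of the lag symmetries on biased lattices.

    Checks C3(n1,n2) = C3(n2,n1) = C3(-n1, n2-n1) = C3(n1-n2, -n2) wherever
    the symmetric images fall on the computed lattice.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_signals):
        x = rng.normal(size=length) ** 3  # skewed, so cumulants are nonzero
        lat = third_order_cumulant(x, max_lag, "biased")
        v = lat.values
        L = max_lag
        worst = max(worst, float(np.abs(v - v.T).max()))
        for n1 in range(-L, L + 1):
            for n2 in range(-L, L + 1):
                for m1, m2 in ((-n1, n2 - n1), (n1 - n2, -n2)):
                    if abs(m1) <= L and abs(m2) <= L:
                        diff = abs(v[n1 + L, n2 + L] - v[m1 + L, m2 + L])
                        worst = max(worst, float(diff))
    return worst


def gaussian_cumulant_scaling(
    seed: int = 0,
    n_seeds: int = 20,
    n_small: int = 25_000,
    n_large: int = 100_000,
    max_lag: int = 5,
) -> dict[str, float]:
    """1/sqrt(N) decay of max|C3| for Gaussian noise, N quadrupled.

    For Gaussian input the population cumulant is zero, so the sample
    lattice is pure estimation noise with root-N standard error: quadrupling
    N should halve the mean max|C3|.  Returns the two means and their ratio.
    """
    ss = np.random.SeedSequence(seed)
    small, large = [], []
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        x = rng.normal(size=n_large)
        small.append(np.abs(third_order_cumulant(x[:n_small], max_lag).values).max())
        large.append(np.abs(third_order_cumulant(x, max_lag).values).max())
    m_small, m_large = float(np.mean(small)), float(np.mean(large))
    return {
        "max_c3_n25k": m_small,
        "max_c3_n100k": m_large,
        "ratio": m_small / m_large,
    }


def _containing_cell(f: float, fs: float, nfft: int) -> int:
    return int(np.floor(f * nfft / fs))


def _principal_argmax(B) -> tuple[int, int]:
    mask = principal_domain_mask(B.nfft, B.sampling_rate)
    mag = np.where(mask, np.abs(B.values), -1.0)
    return tuple(int(v) for v in np.unravel_index(np.argmax(mag), mag.shape))


def qpc_detection_rates(
    seed: int = 0,
    n_seeds: int = 10,
    spec: SyntheticSpec = AGGRESSIVE_SPEC,
    nfft: int = 256,
) -> dict[str, float]:
    """Fraction of seeds whose principal-domain argmax hits the (f1,f2) cell.

    Runs the direct and indirect estimators on the same coupled episodes;
    reports each hit rate and their argmax agreement rate.  The triad cell
    in the principal domain (w2 <= w1) is (cell(max(f1,f2)), cell(min)).
    """
    rng = np.random.default_rng(seed)
    ep_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    fs = spec.sampling_rate
    hi = _containing_cell(max(spec.f1, spec.f2), fs, nfft)
    lo = _containing_cell(min(spec.f1, spec.f2), fs, nfft)
    hits_d = hits_i = agree = 0
    max_lag = int(round(0.05 * fs))
    for s in ep_seeds:
        ep = generate_coupled_episode(replace(spec, seed=int(s)))
        Bd = bispectrum_direct(ep, segment_length=256, nfft=nfft)
        c3 = third_order_cumulant(ep, max_lag=max_lag)
        Bi = bispectrum_indirect(c3, nfft=nfft)
        cd, ci = _principal_argmax(Bd), _principal_argmax(Bi)
        hits_d += cd == (hi, lo)
        hits_i += ci == (hi, lo)
        agree += cd == ci
    return {
        "direct_hit_rate": hits_d / n_seeds,
        "indirect_hit_rate": hits_i / n_seeds,
        "argmax_agreement_rate": agree / n_seeds,
    }


def _episode_D(ep, nfft: int = 256) -> float:
    return qpc_quantity(bispectrum_direct(ep, segment_length=256, nfft=nfft)).D


def qpc_contrast(
    seed: int = 0,
    n_pairs: int = 50,
    spec: SyntheticSpec = AGGRESSIVE_SPEC,
) -> dict[str, float]:
    """Matched-seed comparison of D for coupled vs uncoupled episodes.

    Returns the fraction of pairs with D(coupled) > D(uncoupled) and the
    mean D of each arm.
    """
    rng = np.random.default_rng(seed)
    pair_seeds = rng.integers(0, 2**31 - 1, size=n_pairs)
    wins = 0
    d_c, d_u = [], []
    for s in pair_seeds:
        sp = replace(spec, seed=int(s))
        dc = _episode_D(generate_coupled_episode(sp))
        du = _episode_D(generate_uncoupled_episode(sp))
        wins += dc > du
        d_c.append(dc)
        d_u.append(du)
    return {
        "win_fraction": wins / n_pairs,
        "mean_D_coupled": float(np.mean(d_c)),
        "mean_D_uncoupled": float(np.mean(d_u)),
    }


def qpc_contrast_by_amplitude(
    seed: int = 0,
    amplitudes: tuple[float, ...] = (0.25, 0.5, 1.0),
    n_seeds: int = 20,
) -> list[float]:
    """Mean D(coupled) - D(uncoupled) at each coupling amplitude.

    The contrast should increase with the coupling amplitude.
    """
    out = []
    for a in amplitudes:
        spec = replace(AGGRESSIVE_SPEC, coupling_amplitude=a)
        r = qpc_contrast(seed=seed, n_pairs=n_seeds, spec=spec)
        out.append(r["mean_D_coupled"] - r["mean_D_uncoupled"])
    return out


def elm_solver_errors(seed: int = 0, n_trials: int = 20) -> dict[str, float]:
    """ELM output-weight solve vs a brute-force normal-equations oracle.

    On random full-column-rank hidden matrices (up to 20 x 10) the
    minimum-norm least-squares solution is unique and solves
    H'H beta = H'Y; the oracle builds it by explicit inversion of H'H.
    Also reports the worst residual/column inner product |H'(H beta - Y)|.
    """
    from hosemg.elm import solve_output_weights

    rng = np.random.default_rng(seed)
    worst_beta = worst_orth = 0.0
    for _ in range(n_trials):
        n = int(rng.integers(8, 21))
        m = int(rng.integers(3, min(n, 10) + 1))
        H = rng.normal(size=(n, m))
        Y = np.zeros((n, 2))
        Y[np.arange(n), rng.integers(0, 2, size=n)] = 1.0
        beta = solve_output_weights(H, Y)
        beta_ref = np.linalg.solve(H.T @ H, H.T @ Y)
        worst_beta = max(worst_beta, float(np.abs(beta - beta_ref).max()))
        resid = H @ beta - Y
        worst_orth = max(worst_orth, float(np.abs(H.T @ resid).max()))
    return {"max_beta_error": worst_beta, "max_residual_orthogonality": worst_orth}


def classification_study(
    seed: int = 0,
    n_seeds: int = 20,
    n_per_class: int = 100,
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """End-to-end synthetic study: median/min test accuracy over replicates.

    Each replicate draws a fresh corpus, split and ELM initialization from
    the replicate seed.
    """
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31 - 1))
        cfg = config or PipelineConfig()
        cfg = replace(
            cfg,
            n_per_class=n_per_class,
            corpus_seed=s,
            split_seed=s + 1,
            elm_seed=s + 2,
        )
        accs.append(run_pipeline(cfg).test_accuracy)
    return {
        "median_test_accuracy": float(np.median(accs)),
        "min_test_accuracy": float(np.min(accs)),
        "mean_test_accuracy": float(np.mean(accs)),
    }


def label_shuffle_null(
    seed: int = 0, n_seeds: int = 20, n_per_class: int = 100
) -> dict[str, float]:
    """Shuffle labels before splitting; accuracy should collapse to chance.

    Features are extracted once (they are label-independent); each replicate
    permutes the labels, resplits and retrains.  Guards against information
    leaking from the labels into the feature or split stages.
    """
    cfg = PipelineConfig(n_per_class=n_per_class, corpus_seed=seed)
    corpus = generate_corpus(n_per_class=n_per_class, seed=seed)
    table = extract_features(corpus, cfg)
    rng = np.random.default_rng(seed + 1)
    accs = []
    for _ in range(n_seeds):
        labels = list(table.labels)
        rng.shuffle(labels)
        shuffled = FeatureTable(features=table.features, labels=labels)
        s = int(rng.integers(0, 2**31 - 1))
        train, test = split_train_test(shuffled, 0.5, seed=s)
        model = elm_train(train, n_hidden=cfg.n_hidden, seed=s + 1)
        accs.append(accuracy(elm_predict(model, test.features), test.labels))
    return {
        "median_shuffled_accuracy": float(np.median(accs)),
        "mean_shuffled_accuracy": float(np.mean(accs)),
    }
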