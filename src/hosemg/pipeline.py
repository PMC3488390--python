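"""End-to-end pipeline: episodes -> QPC feature D -> 50/50 split -> ELM.

The study configuration is a 1-input / 40-hidden / 2-output sigmoid ELM
fed with the scalar bispectral feature D per channel-episode, trained and
tested on a random stratified 50%-50% split.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from sklearn.model_selection import train_test_split

from hosemg.elm import ELMModel, FeatureTable, accuracy, elm_predict, elm_train
from hosemg.hos import (
    bispectrum_direct,
    bispectrum_indirect,
    qpc_quantity,
    third_order_cumulant,
)
from hosemg.io_uci import Episode, read_directory
from hosemg.synthetic import AGGRESSIVE_SPEC, NORMAL_SPEC, LabeledEpisodeSet, generate_corpus

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunReport",
    "extract_features",
    "split_train_test",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML."""

    data_source: str = "synthetic"  # "synthetic" | "uci_dir"
    uci_dir: str | None = None
    sampling_rate: float = 1000.0
    n_per_class: int = 100
    corpus_seed: int = 0
    # bispectrum estimator settings
    estimator: str = "direct"  # "direct" | "indirect"
    segment_length: int = 256
    nfft: int = 256
    overlap_fraction: float = 0.5
    window_seconds: float = 0.05  # indirect: lag-window duration -> max_lag
    variance_normalize: bool = False
    channel_mode: str = "per_channel"  # "per_channel" | "summed"
    # classifier settings
    n_hidden: int = 40
    activation: str = "sigmoid"
    elm_seed: int = 0
    split_fraction: float = 0.5
    split_seed: int = 0

    def __post_init__(self) -> None:
        if self.data_source not in ("synthetic", "uci_dir"):
            raise ValueError("data_source must be 'synthetic' or 'uci_dir'")
        if self.data_source == "uci_dir" and not self.uci_dir:
            raise ValueError("data_source='uci_dir' requires uci_dir")
        if self.estimator not in ("direct", "indirect"):
            raise ValueError("estimator must be 'direct' or 'indirect'")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.channel_mode not in ("per_channel", "summed"):
            raise ValueError("channel_mode must be 'per_channel' or 'summed'")

    @property
    def max_lag(self) -> int:
        return int(round(self.window_seconds * self.sampling_rate))

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunReport:
    config: PipelineConfig
    class_counts: dict[str, int]
    train_accuracy: float
    test_accuracy: float
    confusion: dict[str, dict[str, int]]  # truth -> predicted -> count
    n_train: int
    n_test: int
    timings: dict[str, float]

    def to_text(self) -> str:
        lines = [
            "hosemg run report",
            "=" * 40,
            f"data source      : {self.config.data_source}",
            f"estimator        : {self.config.estimator}",
            f"samples per class: {self.class_counts}",
            f"train/test sizes : {self.n_train}/{self.n_test}",
            f"train accuracy   : {self.train_accuracy:.4f}",
            f"test accuracy    : {self.test_accuracy:.4f}",
            "confusion (truth -> predicted):",
        ]
        for truth, row in self.confusion.items():
            lines.append(f"  {truth:12s}: {row}")
        lines.append(
            "seeds (corpus/split/elm): "
            f"{self.config.corpus_seed}/{self.config.split_seed}/{self.config.elm_seed}"
        )
        for stage, sec in self.timings.items():
            lines.append(f"  {stage:12s}: {sec:.3f} s")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["config"] = asdict(self.config)
        return d


def episode_qpc(episode: Episode, config: PipelineConfig) -> float:
    """Compute the scalar QPC feature D for one episode."""
    x = episode
    if config.variance_normalize:
        sd = float(np.std(episode.samples))
        if sd > 0:
            x = Episode(
                samples=episode.samples / sd,
                sampling_rate=episode.sampling_rate,
                channel_name=episode.channel_name,
                action=episode.action,
                label=episode.label,
            )
    if config.estimator == "direct":
        B = bispectrum_direct(
            x,
            segment_length=config.segment_length,
            nfft=config.nfft,
            overlap_fraction=config.overlap_fraction,
        )
    else:
        c3 = third_order_cumulant(x, max_lag=config.max_lag, estimator="biased")
        nfft = max(config.nfft, 2 * config.max_lag + 1)
        B = bispectrum_indirect(c3, nfft=nfft)
    return qpc_quantity(B).D


def extract_features(
    episodes: LabeledEpisodeSet, config: PipelineConfig
) -> FeatureTable:
    """Per channel-episode D (per_channel) or per-recording summed D (summed).

    Episodes shorter than the analysis window are skipped with a warning;
    an all-skipped corpus is an error.
    """
    window = (
        config.segment_length
        if config.estimator == "direct"
        else 2 * config.max_lag + 1
    )
    feats: list[float] = []
    labels: list[str] = []
    skipped = 0
    if config.channel_mode == "summed":
        groups: dict[tuple[str, str], list[float]] = {}
        order: list[tuple[str, str]] = []
    for ep, lab in zip(episodes.episodes, episodes.labels):
        if len(ep) < window:
            log.warning(
                "skipping %s/%s: length %d < analysis window %d",
                ep.action,
                ep.channel_name,
                len(ep),
                window,
            )
            skipped += 1
            continue
        d = episode_qpc(ep, config)
        if config.channel_mode == "summed":
            key = (ep.recording_id or f"{ep.action}", lab)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(d)
        else:
            feats.append(d)
            labels.append(lab)
    if config.channel_mode == "summed":
        for key in order:
            feats.append(float(np.sum(groups[key])))
            labels.append(key[1])
    if not feats:
        raise ValueError(
            f"all {skipped} episodes shorter than the analysis window"
        )
    if skipped:
        log.warning("extract_features: skipped %d short episodes", skipped)
    return FeatureTable(features=np.asarray(feats)[:, None], labels=labels)


def split_train_test(
    table: FeatureTable, fraction: float = 0.5, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified-by-class random split; deterministic under ``seed``."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    counts = {c: table.labels.count(c) for c in table.classes}
    thin = [c for c, n in counts.items() if n < 2]
    if thin:
        raise ValueError(f"class(es) with fewer than 2 samples: {thin}")
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=fraction,
        random_state=seed % (2**32),
        stratify=np.asarray(table.labels),
    )
    def take(ix: np.ndarray) -> FeatureTable:
        return FeatureTable(
            features=table.features[ix],
            labels=[table.labels[i] for i in ix],
        )
    return take(train_idx), take(test_idx)


def _confusion(truth: list[str], pred: list[str], classes: list[str]):
    table = {t: {p: 0 for p in classes} for t in classes}
    for t, p in zip(truth, pred):
        table[t][p] += 1
    return table


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Load or synthesize episodes, extract D, split, train/test the ELM."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    try:
        if config.data_source == "synthetic":
            corpus = generate_corpus(
                n_per_class=config.n_per_class, seed=config.corpus_seed
            )
        else:
            eps = read_directory(config.uci_dir, config.sampling_rate)
            corpus = LabeledEpisodeSet(
                episodes=eps, labels=[e.label for e in eps]
            )
    except Exception as exc:
        raise RuntimeError(f"[load] {exc}") from exc
    timings["load"] = time.perf_counter() - t0
    log.info("loaded %d episodes", len(corpus))

    t0 = time.perf_counter()
    try:
        table = extract_features(corpus, config)
    except Exception as exc:
        raise RuntimeError(f"[features] {exc}") from exc
    timings["features"] = time.perf_counter() - t0
    log.info("extracted %d features (width %d)", len(table), table.features.shape[1])

    t0 = time.perf_counter()
    try:
        train, test = split_train_test(
            table, fraction=config.split_fraction, seed=config.split_seed
        )
        model = elm_train(
            train,
            n_hidden=config.n_hidden,
            activation=config.activation,
            seed=config.elm_seed,
        )
        train_acc = accuracy(elm_predict(model, train.features), train.labels)
        pred = elm_predict(model, test.features)
        test_acc = accuracy(pred, test.labels)
    except Exception as exc:
        raise RuntimeError(f"[classify] {exc}") from exc
    timings["classify"] = time.perf_counter() - t0
    log.info("train acc %.4f / test acc %.4f", train_acc, test_acc)

    counts = {c: table.labels.count(c) for c in table.classes}
    return RunReport(
        config=config,
        class_counts=counts,
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        confusion=_confusion(test.labels, pred, table.classes),
        n_train=len(train),
        n_test=len(test),
        timings=timings,
    )
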