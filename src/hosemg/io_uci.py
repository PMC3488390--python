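"""Reader/writer for the UCI "EMG physical action" plain-text dialect.

Each recording is a plain-text file with one row per sample and one numeric
column per muscle channel (ch1..ch8 in the original archive), separated by
whitespace or commas.  The class label (aggressive/normal) is carried by the
directory layout, not the file contents, so the reader infers it from path
components and accepts an explicit override.  Sampling rate is not stored in
the files either and must be supplied by the caller (1000 Hz nominal: the
recordings are about 10,000 samples over 10 s).
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

LABELS = ("aggressive", "normal", "unknown")
DEFAULT_SAMPLING_RATE = 1000.0


@dataclass
class Episode:
    """One channel's uniformly sampled signal.

    samples are raw amplitudes (arbitrary units); the mean is *not* removed
    at load time — centering is an explicit analysis stage.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    channel_name: str = "ch1"
    action: str = ""
    label: str = "unknown"
    recording_id: str = ""
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("episode needs a non-empty 1-D sample vector")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("episode contains non-finite samples")

    @property
    def duration(self) -> float:
        """Episode length in seconds."""
        return self.samples.size / self.sampling_rate

    def __len__(self) -> int:
        return self.samples.size


def infer_label_from_path(path: str | os.PathLike) -> str:
    """Map path components containing "normal"/"aggressive" to a label."""
    parts = [p.lower() for p in os.path.normpath(os.fspath(path)).split(os.sep)]
    for part in reversed(parts):
        if "aggressive" in part:
            return "aggressive"
        if "normal" in part:
            return "normal"
    return "unknown"


def _infer_action_from_path(path: str) -> str:
    parent = os.path.basename(os.path.dirname(os.path.abspath(path)))
    return parent if parent else ""


def _tokenize(line: str) -> list[str]:
    if "," in line:
        return [t for t in (tok.strip() for tok in line.split(",")) if t]
    return line.split()


def read_action_file(
    path: str | os.PathLike,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    label: str | None = None,
    action: str | None = None,
) -> list[Episode]:
    """Read one action file; return one Episode per column.

    Columns become channels ch1..chK in order.  Rows holding non-finite
    values (NaN/Inf) are dropped and counted on each returned episode.
    Ragged rows and non-numeric tokens are errors naming the offending line.
    """
    path = os.fspath(path)
    if not sampling_rate > 0:
        raise ValueError("sampling_rate must be positive")
    rows: list[list[float]] = []
    n_cols: int | None = None
    n_dropped = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = _tokenize(line)
            if n_cols is None:
                n_cols = len(toks)
            elif len(toks) != n_cols:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(toks)} columns, expected {n_cols})"
                )
            try:
                vals = [float(t) for t in toks]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric token at line {lineno}: {exc}"
                ) from None
            if all(math.isfinite(v) for v in vals):
                rows.append(vals)
            else:
                n_dropped += 1
    if not rows:
        raise ValueError(f"{path}: no numeric data rows")
    if n_dropped:
        log.warning("%s: dropped %d rows with non-finite values", path, n_dropped)
    data = np.asarray(rows, dtype=float)
    if label is None:
        label = infer_label_from_path(path)
    if action is None:
        action = _infer_action_from_path(path)
    return [
        Episode(
            samples=data[:, j],
            sampling_rate=sampling_rate,
            channel_name=f"ch{j + 1}",
            action=action,
            label=label,
            recording_id=path,
            n_dropped_rows=n_dropped,
        )
        for j in range(data.shape[1])
    ]


def write_action_file(
    episodes: list[Episode], path: str | os.PathLike, fmt: str = "%.17g"
) -> str:
    """Write episodes as columns of a plain-text file (UCI dialect).

    The default format preserves doubles exactly, so read(write(x)) is an
    identity on the samples.
    """
    if not episodes:
        raise ValueError("cannot write an empty episode list")
    lengths = {len(e) for e in episodes}
    if len(lengths) != 1:
        raise ValueError(f"episodes have unequal lengths {sorted(lengths)}")
    path = os.fspath(path)
    data = np.column_stack([e.samples for e in episodes])
    np.savetxt(path, data, fmt=fmt, delimiter="\t")
    return path


def read_directory(
    root: str | os.PathLike, sampling_rate: float = DEFAULT_SAMPLING_RATE
) -> list[Episode]:
    """Recurse a directory of action files; labels come from the path."""
    root = os.fspath(root)
    episodes: list[Episode] = []
    for dirpath, _dirnames, filenames in sorted(os.walk(root)):
        for name in sorted(filenames):
            if not name.lower().endswith((".txt", ".csv", ".dat", ".log")):
                continue
            episodes.extend(
                read_action_file(os.path.join(dirpath, name), sampling_rate)
            )
    if not episodes:
        raise ValueError(f"no readable action files under {root}")
    return episodes
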