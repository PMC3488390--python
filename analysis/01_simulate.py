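#!/usr/bin/env python
"""Simulate the synthetic study corpus and summarize it.

Generates the default labeled corpus (phase-coupled low-frequency triads
for the aggressive class, uncoupled triads for the normal class), and
writes per-episode summary statistics to results/corpus_summary.csv.
The raw waveforms are not kept — they are regenerated deterministically
from the seed wherever needed.
"""

import os

import numpy as np
import pandas as pd

from hosemg.synthetic import AGGRESSIVE_SPEC, NORMAL_SPEC, generate_corpus

N_PER_CLASS = 50
SEED = 20260920

os.makedirs("results", exist_ok=True)
corpus = generate_corpus(N_PER_CLASS, seed=SEED)

rows = []
for ep, lab in zip(corpus.episodes, corpus.labels):
    rows.append(
        {
            "recording_id": ep.recording_id,
            "label": lab,
            "n_samples": len(ep),
            "duration_s": ep.duration,
            "rms": float(np.sqrt(np.mean(ep.samples**2))),
            "skewness_proxy": float(
                np.mean((ep.samples - ep.samples.mean()) ** 3)
                / np.std(ep.samples) ** 3
            ),
        }
    )
df = pd.DataFrame(rows)
df.to_csv("results/corpus_summary.csv", index=False)

print(f"simulated {len(df)} episodes ({N_PER_CLASS} per class), seed={SEED}")
print(df.groupby("label")[["rms", "skewness_proxy"]].mean().round(4))
print(
    "\nThe aggressive class (triad below 100 Hz, phases locked) shows a "
    "clearly nonzero third moment;\nthe normal class (independent triad "
    "phase) does not - the premise of the bispectral feature."
)
print("wrote results/corpus_summary.csv")
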