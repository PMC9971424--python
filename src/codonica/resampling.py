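"""Significance procedures for the between-class synonymous share.

Two procedures, both re-running the internal-CA statistic per replicate:

* size-matched subsampling — the larger class is repeatedly downsampled to
  a fixed size (the smaller class kept intact) to check that the observed
  between-class synonymous percentage is not an artifact of unequal class
  sizes;
* label permutation — gene labels are randomly reassigned (class sizes
  preserved) to build the chance distribution of the statistic.

Reproducibility contract: replicate i draws from substream i of a spawned
``numpy.random.SeedSequence``, so results are bitwise stable under the same
seed and unaffected by replicate-level parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ica import CodonUsageTable, between_class_synonymous_pct, ca_inertia, table_codes


@dataclass
class PermutationResult:
    observed: float
    replicates: list[float]
    mean: float
    sd: float
    empirical_p: float
    n_iter: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "mean": self.mean,
            "sd": self.sd,
            "empirical_p": self.empirical_p,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }


def _result(observed: float, reps: list[float], n_iter: int, seed: int) -> PermutationResult:
    arr = np.asarray(reps)
    p = (1 + int((arr >= observed).sum())) / (n_iter + 1)
    return PermutationResult(observed, reps, float(arr.mean()),
                             float(arr.std(ddof=1)) if n_iter > 1 else 0.0,
                             float(p), n_iter, seed)


def _substreams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def subsample_null(table: CodonUsageTable, sample_size: int, n_iter: int = 1000,
                   seed: int = 0, sampled_class=None) -> PermutationResult:
    """Downsample the larger class to *sample_size* per replicate and
    recompute the between-class synonymous percentage on the reduced table."""
    counts, class_codes, block_codes = table_codes(table)
    labels = pd.Categorical(table.row_class)
    sizes = pd.Series(labels).value_counts()
    if sampled_class is None:
        sampled_class = sizes.idxmax()
    pool = np.flatnonzero(np.asarray(labels) == sampled_class)
    keep = np.flatnonzero(np.asarray(labels) != sampled_class)
    if sample_size > len(pool):
        raise ValueError(f"sample_size {sample_size} > class size {len(pool)}")

    observed = between_class_synonymous_pct(counts, class_codes, block_codes)
    reps = []
    for rng in _substreams(seed, n_iter):
        chosen = pool[rng.choice(len(pool), size=sample_size, replace=False)]
        rows = np.concatenate([keep, chosen])
        sub = counts[rows]
        total, _ = ca_inertia(sub, n_eig=0)
        reps.append(between_class_synonymous_pct(
            sub, class_codes[rows], block_codes, total))
    return _result(observed, reps, n_iter, seed)


def label_permutation(table: CodonUsageTable, n_iter: int = 1000,
                      seed: int = 0) -> PermutationResult:
    """Shuffle class labels (sizes preserved) per replicate and recompute the
    between-class synonymous percentage against the fixed table."""
    counts, class_codes, block_codes = table_codes(table)
    if class_codes.max() < 1:
        raise ValueError("need at least 2 classes")
    total, _ = ca_inertia(counts, n_eig=0)
    observed = between_class_synonymous_pct(counts, class_codes, block_codes, total)
    reps = []
    for rng in _substreams(seed, n_iter):
        perm = rng.permutation(class_codes)
        reps.append(between_class_synonymous_pct(counts, perm, block_codes, total))
    return _result(observed, reps, n_iter, seed)
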