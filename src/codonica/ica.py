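"""Internal correspondence analysis of a genes x codons count table.

Correspondence analysis measures the chi-square inertia of a contingency
table, ``sum((f_gc - f_g. f_.c)^2 / (f_g. f_.c))``. Internal CA partitions
the rows (genes) into classes and the columns (codons) into amino-acid
blocks and decomposes the total inertia, exactly additively, into the four
cross components

    BB  between-class x between-block   (amino-acid usage differs between classes)
    BW  between-class x within-block    (synonymous usage differs between classes)
    WB  within-class  x between-block
    WW  within-class  x within-block

via nested centerings (Lobry & Chessel). Nine elementary analyses — rows in
{total, between-class, within-class} crossed with columns in {total,
between-block, within-block} — each carry an inertia, its percentage of the
total, and the leading eigenvalues of the corresponding standardized
residual matrix.

The BW share is the quantity of interest for two gene classes with shared
amino-acid composition: it isolates the purely synonymous between-class
signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_code import CODON_TO_AA, INCLUDED_59, SENSE_CODONS

logger = logging.getLogger(__name__)

_EIG_CLIP = 1e-12


@dataclass
class CodonUsageTable:
    """Genes x codons counts with a row-class and a column-block partition."""

    counts: pd.DataFrame  # genes x codons, non-negative
    row_class: pd.Series  # gene -> class label
    col_block: pd.Series  # codon -> amino acid

    def __post_init__(self) -> None:
        if (self.counts.sum(axis=1) <= 0).any():
            raise ValueError("every row must have a positive sum")
        if not self.row_class.index.equals(self.counts.index):
            self.row_class = self.row_class.loc[self.counts.index]
        if not self.col_block.index.equals(self.counts.columns):
            self.col_block = self.col_block.loc[self.counts.columns]


@dataclass
class ElementaryAnalysis:
    inertia: float
    pct_of_total: float
    eigenvalues: list[float]


@dataclass
class InertiaDecomposition:
    total_inertia: float
    components: dict[str, float]          # BB, BW, WB, WW
    percentages: dict[str, float]         # same keys, % of total
    elementary: dict[tuple[str, str], ElementaryAnalysis]

    def to_dict(self) -> dict:
        return {
            "total_inertia": self.total_inertia,
            "components": self.components,
            "percentages": self.percentages,
            "elementary": {
                f"{r}|{c}": {
                    "inertia": e.inertia,
                    "pct_of_total": e.pct_of_total,
                    "eigenvalues": e.eigenvalues,
                }
                for (r, c), e in self.elementary.items()
            },
        }


def build_table(counts: pd.DataFrame, grouping, codons: int | None = 59) -> CodonUsageTable:
    """Assemble a CodonUsageTable from a genes x codons count matrix.

    *grouping* maps gene -> class label (dict or Series). *codons* selects
    the included codon set: 59 (drop Met, Trp; the default) or 61 (all sense
    codons). Genes with zero included codons are dropped with a log record;
    classes with fewer than two genes raise.
    """
    included = list(INCLUDED_59 if codons in (None, 59) else SENSE_CODONS)
    sub = counts.loc[:, [c for c in included if c in counts.columns]].copy()
    row_sums = sub.sum(axis=1)
    dropped = sub.index[row_sums <= 0]
    if len(dropped):
        logger.info("dropping %d genes with zero included codons: %s",
                    len(dropped), list(dropped[:10]))
        sub = sub.loc[row_sums > 0]
    labels = pd.Series(grouping).loc[sub.index]
    sizes = labels.value_counts()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValueError(f"class with <2 genes: {list(small.index)}")
    blocks = pd.Series({c: CODON_TO_AA[c] for c in sub.columns})
    return CodonUsageTable(sub, labels, blocks)


def _inertia_and_eigs(X: np.ndarray, row_mass: np.ndarray, col_mass: np.ndarray,
                      n_eig: int = 10) -> tuple[float, list[float]]:
    S = X / np.sqrt(np.outer(row_mass, col_mass))
    inertia = float((S * S).sum())
    sv = np.linalg.svd(S, compute_uv=False)
    eig = sv * sv
    eig[eig < _EIG_CLIP] = 0.0
    return inertia, [float(v) for v in eig[:n_eig]]


def ca_inertia(table: CodonUsageTable | pd.DataFrame | np.ndarray,
               n_eig: int = 10) -> tuple[float, list[float]]:
    """Total chi-square inertia (chi2/N) and CA eigenvalues of a table."""
    M = table.counts if isinstance(table, CodonUsageTable) else table
    N = np.asarray(M, dtype=float)
    total = N.sum()
    if total <= 0:
        return 0.0, []
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep_r, keep_c = r > 0, c > 0
    P, r, c = P[np.ix_(keep_r, keep_c)], r[keep_r], c[keep_c]
    return _inertia_and_eigs(P - np.outer(r, c), r, c, n_eig)


def _partition_matrices(table: CodonUsageTable):
    """Aggregation matrices and masses for the nested decomposition."""
    N = table.counts.to_numpy(dtype=float)
    P = N / N.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)

    classes = pd.Categorical(table.row_class)
    Z = np.zeros((len(classes.categories), len(r)))
    Z[classes.codes, np.arange(len(r))] = 1.0

    blocks = pd.Categorical(table.col_block)
    M = np.zeros((len(c), len(blocks.categories)))
    M[np.arange(len(c)), blocks.codes] = 1.0

    return P, r, c, Z, M, classes.codes, blocks.codes


def ica_decompose(table: CodonUsageTable, n_eig: int = 10) -> InertiaDecomposition:
    """Four-component inertia decomposition plus the nine elementary analyses."""
    P, r, c, Z, M, class_codes, _ = _partition_matrices(table)

    r_K = Z @ r                      # class masses
    c_B = M.T @ c                    # block masses
    P_K = Z @ P                      # class x codon
    # class profiles expanded back to genes: E[g, :] = r_g * profile(class of g)
    Q = P_K / r_K[:, None]
    E = r[:, None] * Q[class_codes]
    W = P - E                        # within-class residual (column sums 0 per gene)

    # column within-block projector: X -> (X @ M) @ R reproduces block totals
    # spread over codons proportionally to codon mass within the block
    R = (M * (c[:, None] / c_B[None, :])).T

    def col_within(X: np.ndarray) -> np.ndarray:
        return X - (X @ M) @ R

    mats = {
        ("total", "total"): (P - np.outer(r, c), r, c),
        ("between_class", "total"): (P_K - np.outer(r_K, c), r_K, c),
        ("within_class", "total"): (W, r, c),
        ("total", "between_block"): (P @ M - np.outer(r, c_B), r, c_B),
        ("between_class", "between_block"): (Z @ P @ M - np.outer(r_K, c_B), r_K, c_B),
        ("within_class", "between_block"): (W @ M, r, c_B),
        ("total", "within_block"): (col_within(P - np.outer(r, c)), r, c),
        ("between_class", "within_block"): (col_within(P_K - np.outer(r_K, c)), r_K, c),
        ("within_class", "within_block"): (col_within(W), r, c),
    }

    total_inertia, _ = _inertia_and_eigs(*mats[("total", "total")], n_eig=n_eig)
    elementary: dict[tuple[str, str], ElementaryAnalysis] = {}
    for key, (X, rm, cm) in mats.items():
        inertia, eigs = _inertia_and_eigs(X, rm, cm, n_eig=n_eig)
        pct = 100.0 * inertia / total_inertia if total_inertia > 0 else 0.0
        elementary[key] = ElementaryAnalysis(inertia, pct, eigs)

    components = {
        "BB": elementary[("between_class", "between_block")].inertia,
        "BW": elementary[("between_class", "within_block")].inertia,
        "WB": elementary[("within_class", "between_block")].inertia,
        "WW": elementary[("within_class", "within_block")].inertia,
    }
    percentages = {
        k: (100.0 * v / total_inertia if total_inertia > 0 else 0.0)
        for k, v in components.items()
    }
    return InertiaDecomposition(total_inertia, components, percentages, elementary)


def between_class_synonymous_pct(counts: np.ndarray, class_codes: np.ndarray,
                                 block_codes: np.ndarray,
                                 total_inertia: float | None = None) -> float:
    """Fast BW share (%): the between-class, within-amino-acid synonymous
    component as a percentage of the table's total inertia.

    Computed from collapsed tables only — BW = inertia(class x codon) −
    inertia(class x block) — which makes permutation loops cheap. Pass
    *total_inertia* to avoid recomputing it when only labels change.
    """
    N = np.asarray(counts, dtype=float)
    if total_inertia is None:
        total_inertia, _ = ca_inertia(N, n_eig=0)
    if total_inertia <= 0:
        return 0.0
    K = class_codes.max() + 1
    Z = np.zeros((K, N.shape[0]))
    Z[class_codes, np.arange(N.shape[0])] = 1.0
    NK = Z @ N
    B = block_codes.max() + 1
    Mb = np.zeros((N.shape[1], B))
    Mb[np.arange(N.shape[1]), block_codes] = 1.0
    i_kc, _ = ca_inertia(NK, n_eig=0)
    i_kb, _ = ca_inertia(NK @ Mb, n_eig=0)
    return 100.0 * (i_kc - i_kb) / total_inertia


def table_codes(table: CodonUsageTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(counts array, class codes, block codes) for the fast statistic."""
    return (
        table.counts.to_numpy(dtype=float),
        np.asarray(pd.Categorical(table.row_class).codes),
        np.asarray(pd.Categorical(table.col_block).codes),
    )
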