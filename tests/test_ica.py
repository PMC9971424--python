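"""Correspondence-analysis inertia and the internal four-way decomposition."""

import numpy as np
import pandas as pd
import pytest

from codonica.genetic_code import DEGENERATE_FAMILIES, INCLUDED_59
from codonica.ica import (
    build_table,
    ca_inertia,
    between_class_synonymous_pct,
    ica_decompose,
    table_codes,
)

from oracles import oracle_inertia


def _random_counts(rng, n_genes=12, low=1, high=30) -> pd.DataFrame:
    data = rng.integers(low, high, size=(n_genes, len(INCLUDED_59)))
    return pd.DataFrame(data, columns=list(INCLUDED_59),
                        index=[f"g{i}" for i in range(n_genes)])


def _labels(index, k=2):
    return pd.Series([f"c{i % k}" for i in range(len(index))], index=index)


class TestBuildTable:
    def test_shape_classes_blocks(self, rng):
        counts = _random_counts(rng, 4)
        table = build_table(counts, _labels(counts.index))
        assert table.counts.shape == (4, 59)
        assert table.row_class.nunique() == 2
        assert table.col_block.nunique() == 18  # degenerate amino acids

    def test_met_only_gene_dropped(self, rng):
        counts = _random_counts(rng, 4)
        counts["ATG"] = 0
        counts.loc["g0", :] = 0
        counts.loc["g0", "ATG"] = 50  # only excluded codons
        table = build_table(counts, pd.Series("x", index=counts.index))
        assert "g0" not in table.counts.index

    def test_small_class_raises(self, rng):
        counts = _random_counts(rng, 3)
        labels = pd.Series(["a", "a", "b"], index=counts.index)
        with pytest.raises(ValueError, match="b"):
            build_table(counts, labels)

    def test_61_codon_mode(self, rng):
        counts = _random_counts(rng, 4)
        counts["ATG"] = 5
        counts["TGG"] = 5
        table = build_table(counts, _labels(counts.index), codons=61)
        assert table.counts.shape[1] == 61


class TestCaInertia:
    def test_independence_is_zero(self):
        row = np.array([3.0, 1.0, 2.0, 4.0])
        M = np.vstack([row, 2 * row, 5 * row])
        inertia, eigs = ca_inertia(M)
        assert inertia == pytest.approx(0.0, abs=1e-14)

    def test_2x2_diagonal(self):
        inertia, eigs = ca_inertia(np.array([[10, 0], [0, 10]]))
        assert inertia == pytest.approx(1.0)
        assert eigs[0] == pytest.approx(1.0)

    def test_matches_double_sum_oracle(self, rng):
        M = rng.integers(0, 25, size=(20, 59))
        inertia, eigs = ca_inertia(M)
        assert inertia == pytest.approx(oracle_inertia(M), abs=1e-12)
        assert inertia == pytest.approx(sum(ca_inertia(M, n_eig=59)[1]), rel=1e-10)

    def test_eigenvalues_nonnegative_sorted(self, rng):
        M = rng.integers(1, 9, size=(8, 12))
        _, eigs = ca_inertia(M)
        assert all(e >= 0 for e in eigs)
        assert eigs == sorted(eigs, reverse=True)


class TestDecomposition:
    def test_additivity_and_margins(self, rng):
        counts = _random_counts(rng, 15)
        table = build_table(counts, _labels(counts.index, 3))
        dec = ica_decompose(table)
        comp = dec.components
        total = dec.total_inertia
        assert sum(comp.values()) == pytest.approx(total, rel=1e-10)
        e = dec.elementary
        assert e[("between_class", "total")].inertia + \
            e[("within_class", "total")].inertia == pytest.approx(total, rel=1e-10)
        assert e[("total", "between_block")].inertia + \
            e[("total", "within_block")].inertia == pytest.approx(total, rel=1e-10)
        # row margin: BB+BW = between-class total, etc.
        assert comp["BB"] + comp["BW"] == pytest.approx(
            e[("between_class", "total")].inertia, rel=1e-10)
        assert comp["BB"] + comp["WB"] == pytest.approx(
            e[("total", "between_block")].inertia, rel=1e-10)

    def test_eigenvalues_sum_to_analysis_inertia(self, rng):
        counts = _random_counts(rng, 10)
        table = build_table(counts, _labels(counts.index))
        dec = ica_decompose(table, n_eig=59)
        for key, analysis in dec.elementary.items():
            assert sum(analysis.eigenvalues) == pytest.approx(
                analysis.inertia, rel=1e-9), key

    def test_identical_class_profiles_no_between_signal(self, rng):
        """Class 2 rows are class 1 rows scaled by 2: collapsed class
        profiles coincide, so all between-class inertia vanishes."""
        half = _random_counts(rng, 6)
        counts = pd.concat([half, 2 * half.set_index(half.index + "_b")])
        labels = pd.Series(["c1"] * 6 + ["c2"] * 6, index=counts.index)
        dec = ica_decompose(build_table(counts, labels))
        assert dec.components["BB"] == pytest.approx(0.0, abs=1e-12)
        assert dec.components["BW"] == pytest.approx(0.0, abs=1e-12)

    def test_synonymous_permutation_hits_only_within_block(self, rng):
        """Permuting synonymous codons within families for class 2 leaves
        amino-acid totals untouched: the between-class signal must be purely
        synonymous (BB = 0, BW > 0)."""
        half = _random_counts(rng, 6)
        permuted = half.copy()
        for codons in DEGENERATE_FAMILIES.values():
            cols = list(codons)
            permuted[cols] = half[cols[1:] + cols[:1]].to_numpy()
        counts = pd.concat([half, permuted.set_index(half.index + "_b")])
        labels = pd.Series(["c1"] * 6 + ["c2"] * 6, index=counts.index)
        dec = ica_decompose(build_table(counts, labels))
        assert dec.components["BB"] == pytest.approx(0.0, abs=1e-12)
        assert dec.components["BW"] > 1e-4

    def test_scale_invariance_of_percentages(self, rng):
        counts = _random_counts(rng, 10)
        labels = _labels(counts.index)
        a = ica_decompose(build_table(counts, labels))
        b = ica_decompose(build_table(counts * 7, labels))
        for key in a.percentages:
            assert a.percentages[key] == pytest.approx(b.percentages[key], rel=1e-9)

    def test_eigenvalue_lists_truncated_at_ten(self, rng):
        counts = _random_counts(rng, 30)
        dec = ica_decompose(build_table(counts, _labels(counts.index)))
        assert all(len(e.eigenvalues) <= 10 for e in dec.elementary.values())

    def test_single_block_degenerate_partition(self, rng):
        """One block only: between-block components collapse to zero, no error."""
        counts = _random_counts(rng, 6).iloc[:, :2]  # GCA/GCC: one family
        table_counts = counts.copy()
        from codonica.ica import CodonUsageTable

        table = CodonUsageTable(
            table_counts, _labels(counts.index),
            pd.Series("A", index=counts.columns))
        dec = ica_decompose(table)
        assert dec.components["BB"] + dec.components["WB"] == pytest.approx(0, abs=1e-12)


def test_fast_statistic_matches_full_decomposition(rng):
    counts = _random_counts(rng, 14)
    table = build_table(counts, _labels(counts.index))
    dec = ica_decompose(table)
    c, cc, bc = table_codes(table)
    fast = between_class_synonymous_pct(c, cc, bc)
    assert fast == pytest.approx(dec.percentages["BW"], rel=1e-9)
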