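"""Codon-usage indices against hand-computed values and brute-force oracles."""

import math

import numpy as np
import pytest

from codonica.codon_metrics import (
    CodonCounts,
    cai,
    cai_weights,
    composition,
    count_codons,
    default_cai_weights,
    enc,
    rscu,
)
from codonica.genetic_code import DEGENERATE_FAMILIES, FAMILIES, INCLUDED_59

from conftest import random_cds
from oracles import oracle_composition, oracle_enc


def counts_of(d: dict) -> CodonCounts:
    return CodonCounts(dict(d), sum(d.values()))


class TestCountCodons:
    def test_stop_not_counted(self):
        assert count_codons("ATGAAATAA").counts == {"ATG": 1, "AAA": 1}

    def test_ambiguous_codon_skipped(self):
        assert count_codons("AAANNNAAA").counts == {"AAA": 2}

    def test_each_sense_codon_once(self):
        seq = "".join(INCLUDED_59)
        c = count_codons(seq)
        assert c.n_codons_used == 59
        assert set(c.counts.values()) == {1}

    def test_frame_violation_raises(self):
        with pytest.raises(ValueError):
            count_codons("ATGA")


class TestEnc:
    def test_one_codon_per_amino_acid_gives_20(self):
        counts = counts_of({codons[0]: 2 for codons in FAMILIES.values()})
        assert enc(counts) == pytest.approx(20.0)

    def test_hand_computed_mixed_usage(self):
        # two-fold families (3,1): F=0.5; four-fold (2,2,0,0): F=1/3;
        # six-fold (2,2,2,0,0,0): F=0.2; Ile absent -> F3=(0.5+1/3)/2
        counts = {}
        for aa, codons in DEGENERATE_FAMILIES.items():
            if aa == "I":
                continue
            if len(codons) == 2:
                counts[codons[0]], counts[codons[1]] = 3, 1
            elif len(codons) == 4:
                counts[codons[0]], counts[codons[1]] = 2, 2
            else:
                for c in codons[:3]:
                    counts[c] = 2
        value = enc(counts_of(counts))
        # 2 + 9/0.5 + 1/(5/12) + 5/(1/3) + 3/0.2 = 52.4
        assert value == pytest.approx(52.4)

    def test_uniform_long_gene_approaches_61(self, rng):
        seq = random_cds(rng, 10_000, start_stop=False)
        value = enc(count_codons(seq))
        assert 60.0 <= value <= 61.0

    def test_insufficient_families_is_missing(self):
        assert math.isnan(enc(counts_of({"AAA": 3, "AAG": 1})))

    def test_monotone_in_evenness_for_two_fold_families(self):
        """Evening out usage within two-fold families never lowers ENC."""
        base = {codons[0]: 6 for codons in DEGENERATE_FAMILIES.values()}
        prev = None
        for split in [(6, 0), (5, 1), (4, 2), (3, 3)]:
            counts = dict(base)
            for aa, codons in DEGENERATE_FAMILIES.items():
                if len(codons) == 2:
                    counts[codons[0]], counts[codons[1]] = split
            value = enc(counts_of({k: v for k, v in counts.items() if v > 0}))
            if prev is not None:
                assert value >= prev
            prev = value


class TestRscu:
    def test_equal_usage_is_one(self):
        counts = counts_of({c: 2 for codons in FAMILIES.values() for c in codons})
        vals = rscu(counts)
        assert all(v == pytest.approx(1.0) for v in vals.values())

    def test_lysine_three_to_one(self):
        vals = rscu(counts_of({"AAA": 3, "AAG": 1}))
        assert vals["AAA"] == pytest.approx(1.5)
        assert vals["AAG"] == pytest.approx(0.5)

    def test_absent_family_is_missing(self):
        vals = rscu(counts_of({"AAA": 1}))
        assert math.isnan(vals["GGG"])

    def test_family_mean_is_one_when_observed(self, rng):
        seq = random_cds(rng, 2000, start_stop=False)
        vals = rscu(count_codons(seq))
        for codons in FAMILIES.values():
            fam = [vals[c] for c in codons]
            if not any(math.isnan(v) for v in fam):
                assert np.mean(fam) == pytest.approx(1.0)


class TestCai:
    def test_weights_nine_to_one(self):
        w = cai_weights(counts_of({"AAA": 9, "AAG": 1})).w
        assert w["AAA"] == pytest.approx(1.0)
        assert w["AAG"] == pytest.approx(1 / 9)

    def test_weights_tie(self):
        w = cai_weights(counts_of({"AAA": 5, "AAG": 5})).w
        assert w["AAA"] == w["AAG"] == pytest.approx(1.0)

    def test_zero_count_smoothing(self):
        w = cai_weights(counts_of({"AAA": 8})).w
        assert w["AAG"] == pytest.approx(0.5 / 8)

    def test_all_optimal_codons_gives_one(self):
        ref = counts_of({"AAA": 9, "AAG": 1})
        w = cai_weights(ref)
        assert cai(counts_of({"AAA": 20}), w) == pytest.approx(1.0)

    def test_geometric_mean_by_hand(self):
        w = cai_weights(counts_of({"AAA": 2, "AAG": 1, "GAA": 1, "GAG": 1}))
        # codons with w = 1 and 0.5 -> sqrt(0.5)
        value = cai(counts_of({"AAA": 1, "AAG": 1}), w)
        assert value == pytest.approx(math.sqrt(0.5))

    def test_met_codon_does_not_change_cai(self):
        w = cai_weights(counts_of({"AAA": 3, "AAG": 1}))
        a = cai(counts_of({"AAA": 1, "AAG": 1}), w)
        b = cai(counts_of({"AAA": 1, "AAG": 1, "ATG": 5}), w)
        assert a == b

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            cai_weights(counts_of({}))


class TestComposition:
    def test_glycine_only(self):
        comp = composition("GGG" * 10)
        assert comp["g3s"] == 1.0
        assert comp["a3s"] == comp["c3s"] == comp["t3s"] == 0.0
        assert comp["gc3"] == 1.0

    def test_gc12_is_mean_of_gc1_gc2(self, rng):
        comp = composition(random_cds(rng, 200))
        assert comp["gc12"] == pytest.approx((comp["gc1"] + comp["gc2"]) / 2)

    def test_matches_bruteforce_on_random_cds(self, rng):
        for _ in range(20):
            seq = random_cds(rng, int(rng.integers(50, 300)), start_stop=False)
            ours, ref = composition(seq), oracle_composition(seq)
            for key, val in ref.items():
                assert ours[key] == pytest.approx(val, abs=1e-12), key

    def test_fractions_in_unit_interval(self, rng):
        for _ in range(10):
            comp = composition(random_cds(rng, 100))
            for key, val in comp.items():
                if not math.isnan(val):
                    assert 0.0 <= val <= 1.0, key


def test_enc_cai_negatively_correlated_on_shared_bias_axis():
    """Genes spread along one preference axis: stronger bias lowers ENC and
    raises CAI, so their rank correlation is negative."""
    from scipy.stats import spearmanr

    from codonica.simulate import SyntheticConfig, simulate_codon_usage

    cfg = SyntheticConfig(n_seg=60, n_meg=60, gc3_sd=1.2)
    counts, _, _ = simulate_codon_usage(cfg, seed=3)
    by_gene = {
        g: counts_of({c: int(n) for c, n in row.items() if n > 0})
        for g, row in counts.iterrows()
    }
    weights = default_cai_weights(by_gene)
    encs = [enc(c) for c in by_gene.values()]
    cais = [cai(c, weights) for c in by_gene.values()]
    assert spearmanr(encs, cais).statistic < 0


def test_enc_matches_oracle_spot(rng):
    for _ in range(5):
        seq = random_cds(rng, 150, start_stop=False)
        c = count_codons(seq)
        assert enc(c) == pytest.approx(oracle_enc(c.counts), abs=1e-12)
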