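import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from apobecsig.apobec_stats import (
    ApobecDefinition,
    ContingencyTable2x2,
    apobec_fraction,
    compare_apobec_fractions,
    fisher_exact_2x2,
    pentanucleotide_freq,
)
from apobecsig.catalogs import CHANNEL_INDEX
from apobecsig.variant_io import ReferenceContext, VariantRecord


class TestApobecDefinition:
    def test_tcn_has_eight_channels(self):
        channels = ApobecDefinition("TCN").channels
        assert len(channels) == 8
        assert set(channels) == {
            f"T[C>{alt}]{b}" for alt in "TG" for b in "ACGT"
        }

    def test_tcw_has_four_channels(self):
        assert set(ApobecDefinition("TCW").channels) == {
            "T[C>T]A", "T[C>T]T", "T[C>G]A", "T[C>G]T"
        }

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            ApobecDefinition("NCN")


class TestApobecFraction:
    def test_simple_counting(self):
        row = np.zeros(96)
        row[CHANNEL_INDEX["T[C>T]A"]] = 4
        row[CHANNEL_INDEX["A[C>A]A"]] = 6
        fr = apobec_fraction(row)
        assert (fr.apobec, fr.total) == (4, 10)
        assert fr.fraction == pytest.approx(0.4)

    def test_all_apobec_row(self):
        row = np.zeros(96)
        for c in ApobecDefinition().channels:
            row[CHANNEL_INDEX[c]] = 5
        assert apobec_fraction(row).fraction == 1.0

    def test_zero_total_flagged(self):
        fr = apobec_fraction(np.zeros(96))
        assert not fr.defined and fr.fraction is None

    def test_partition_is_exact(self, rng):
        row = rng.integers(0, 20, 96).astype(float)
        fr = apobec_fraction(row)
        assert fr.apobec + (fr.total - fr.apobec) == fr.total == row.sum()

    def test_generator_mass_recovered(self, six_signatures):
        from apobecsig.synthetic_data import simulate_catalog

        # 35% APOBEC-channel mass: mix sbs2-like with flat
        defn = ApobecDefinition()
        mix = np.array([0.3, 0.0, 0.7, 0.0, 0.0, 0.0])
        p = six_signatures.profiles @ mix
        true_mass = p[defn.channel_indices].sum()
        row, _ = simulate_catalog(six_signatures, mix, 2000, seed=13)
        fr = apobec_fraction(row, defn)
        se = math.sqrt(true_mass * (1 - true_mass) / 2000)
        assert abs(fr.fraction - true_mass) < 4 * se


def _oracle_two_sided_p(a, b, c, d):
    """Brute-force enumeration with exact integer weights."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    obs = weights[a]
    num = sum(w for w in weights.values() if w * 10_000_000 <= obs * 10_000_001)
    return float(Fraction(num, sum(weights.values())))


class TestFisher:
    def test_symmetric_table(self):
        r = fisher_exact_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert r.p == 1.0
        assert r.odds_ratio == pytest.approx(1.0, abs=1e-6)
        assert r.ci_low < 1 < r.ci_high

    def test_zero_cell_boundary(self):
        r = fisher_exact_2x2(ContingencyTable2x2(0, 8, 5, 7))
        assert r.odds_ratio == 0.0
        assert r.ci_low == 0.0

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 40, 4))
            ours = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d), compute_ci=False)
            _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
            assert ours.p == pytest.approx(p_scipy, abs=1e-9)

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(0, 30, 4))
            ours = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d), compute_ci=False)
            assert abs(ours.p - _oracle_two_sided_p(a, b, c, d)) < 1e-12

    def test_conditional_mle_bracketed_by_ci(self, rng):
        for _ in range(10):
            a, b, c, d = (int(v) + 1 for v in rng.integers(0, 25, 4))
            r = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            assert r.ci_low <= r.odds_ratio <= r.ci_high

    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_row_and_column_swap_invariances(self, cells):
        a, b, c, d = cells
        base = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d), compute_ci=False)
        both = fisher_exact_2x2(ContingencyTable2x2(d, c, b, a), compute_ci=False)
        assert base.p == pytest.approx(both.p, abs=1e-12)
        rows = fisher_exact_2x2(ContingencyTable2x2(c, d, a, b), compute_ci=False)
        assert rows.p == pytest.approx(base.p, abs=1e-12)
        if all(v > 0 for v in (a, b, c, d)):
            assert rows.odds_ratio_sample == pytest.approx(1 / base.odds_ratio_sample)


class TestCompareFractions:
    def test_identical_groups_give_p_one(self):
        res = compare_apobec_fractions(
            {"ctrl": (50, 150), "ko": (50, 150)}, reference="ctrl"
        )
        assert res["ko"].p == 1.0 and res["ko"].p_adjusted == 1.0

    def test_bonferroni_arithmetic(self):
        groups = {"ctrl": (30, 170), "a": (55, 145), "b": (31, 169), "c": (29, 171)}
        res = compare_apobec_fractions(groups, reference="ctrl")
        for r in res.values():
            assert r.m == 3
            assert r.p_adjusted == min(1.0, 3 * r.p)

    def test_power_on_shifted_fraction(self):
        """0.20 -> 0.30 APOBEC fraction at 1500 mutations/group is detected
        in nearly every seeded replicate."""
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            ctrl_ap = rng.binomial(1500, 0.20)
            ko_ap = rng.binomial(1500, 0.30)
            res = compare_apobec_fractions(
                {"ctrl": (ctrl_ap, 1500 - ctrl_ap), "ko": (ko_ap, 1500 - ko_ap)},
                reference="ctrl",
            )
            if res["ko"].p_adjusted < 0.05:
                hits += 1
        assert hits >= 95

    def test_missing_reference_rejected(self):
        with pytest.raises(KeyError):
            compare_apobec_fractions({"a": (1, 2)}, reference="ctrl")


class TestPentanucleotide:
    def _ref(self):
        #            123456789
        return ReferenceContext({"c": "GATCGGATTCATAACGGA"})

    def test_direct_ntcnn_match(self):
        # C>T at pos 4, 5-mer ATCGG
        ref = self._ref()
        v = VariantRecord("s", "c", 4, "C", "T", "PASS", 0.5)
        m = pentanucleotide_freq([v], ref)
        assert m.n_kmers == 1
        for pos, base in zip((-2, -1, 0, 1, 2), "ATCGG"):
            assert m.freq(pos, base) == 1.0

    def test_non_t_minus1_filtered_out(self):
        # C>T at pos 15 has 5-mer AACGG: position -1 is A, not T
        m = pentanucleotide_freq(
            [VariantRecord("s", "c", 15, "C", "T", "PASS", 0.5)], self._ref()
        )
        assert m.n_kmers == 0
        assert m.skipped == {"not_ntcnn": 1}

    def test_purine_strand_reverse_complemented(self):
        # G>A at genomic 5-mer CCGAT (pos 3 of GCCGATG) -> ATCGG retained
        ref = ReferenceContext({"c": "GCCGATG"})
        v = VariantRecord("s", "c", 4, "G", "A", "PASS", 0.5)
        m = pentanucleotide_freq([v], ref)
        assert m.n_kmers == 1
        assert m.freq(-2, "A") == m.freq(-1, "T") == m.freq(0, "C") == 1.0
        assert m.freq(1, "G") == m.freq(2, "G") == 1.0

    def test_mirror_strands_contribute_identically(self, small_reference, six_signatures):
        from apobecsig.synthetic_data import simulate_catalog, simulate_variants

        counts, _ = simulate_catalog(six_signatures, [0.5, 0.5, 0, 0, 0, 0], 400, seed=21)
        sim = simulate_variants(counts, small_reference, sample_id="s", seed=22)
        m = pentanucleotide_freq(sim.records, small_reference)
        assert m.n_kmers > 0
        # NTCNN contract regardless of which strand hosted the variant
        assert m.freq(-1, "T") == 1.0
        assert m.freq(0, "C") == 1.0
        np.testing.assert_allclose(m.frequencies.sum(axis=1), 1.0)

    def test_non_ct_cg_substitutions_ignored(self):
        ref = self._ref()
        v = VariantRecord("s", "c", 4, "C", "A", "PASS", 0.5)
        m = pentanucleotide_freq([v], ref)
        assert m.n_kmers == 0 and m.skipped == {"not_ct_or_cg": 1}
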