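import numpy as np
import pytest

from apobecsig.catalogs import CHANNELS, CHANNEL_INDEX, build_catalog, parse_channel
from apobecsig.variant_io import ContextUnavailable, filter_variants, subtract_parental
from apobecsig.synthetic_data import (
    CohortConfig,
    make_reference,
    make_signatures,
    simulate_catalog,
    simulate_cohort,
    simulate_controls,
    simulate_variants,
    write_reference,
)


class TestReference:
    def test_deterministic_per_seed(self):
        a = make_reference(length=2000, seed=4)
        b = make_reference(length=2000, seed=4)
        assert a.fetch("chrS", 1, 2000) == b.fetch("chrS", 1, 2000)
        c = make_reference(length=2000, seed=5)
        assert a.fetch("chrS", 1, 2000) != c.fetch("chrS", 1, 2000)

    def test_gc_content_binomial(self):
        length = 100_000
        ref = make_reference(length=length, gc=0.5, seed=1)
        seq = ref.fetch("chrS", 1, length)
        gc = sum(1 for b in seq if b in "GC")
        sd = (length * 0.25) ** 0.5
        assert abs(gc - length * 0.5) < 3 * sd

    def test_edge_lookups_raise(self):
        ref = make_reference(length=1000, seed=0)
        with pytest.raises(ContextUnavailable):
            ref.get_context("chrS", 1, 2)
        with pytest.raises(ContextUnavailable):
            ref.get_context("chrS", 1000, 2)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_reference(length=500)

    def test_fasta_round_trip(self, tmp_path):
        from apobecsig.variant_io import ReferenceContext

        ref = make_reference(length=3000, seed=6)
        write_reference(ref, tmp_path / "ref.fa")
        assert (tmp_path / "ref.fa.fai").exists()
        back = ReferenceContext.from_fasta(tmp_path / "ref.fa")
        assert back.contig_lengths == {"chrS": 3000}
        assert back.fetch("chrS", 100, 200) == ref.fetch("chrS", 100, 200)


class TestSignatures:
    def test_flat_is_uniform(self):
        sigs = make_signatures(["flat"])
        np.testing.assert_allclose(sigs.profiles[:, 0], 1 / 96)

    def test_apobec_like_mass_concentration(self):
        sigs = make_signatures(["sbs2-like", "sbs13-like"])
        tcn_ct = [CHANNEL_INDEX[f"T[C>T]{b}"] for b in "ACGT"]
        tcn_cg = [CHANNEL_INDEX[f"T[C>G]{b}"] for b in "ACGT"]
        assert sigs.profiles[tcn_ct, 0].sum() >= 0.95
        assert sigs.profiles[tcn_cg, 1].sum() >= 0.95

    def test_c_to_a_skew(self):
        sigs = make_signatures(["c-to-a-skewed"])
        ca = [i for i, c in enumerate(CHANNELS) if parse_channel(c)[1:3] == ("C", "A")]
        assert sigs.profiles[ca, 0].sum() == pytest.approx(0.9)

    def test_column_sums_one(self, six_signatures):
        np.testing.assert_allclose(six_signatures.profiles.sum(axis=0), 1.0, atol=1e-9)

    def test_random_profiles_seeded(self):
        a = make_signatures(["random-1"], seed=2)
        b = make_signatures(["random-1"], seed=2)
        np.testing.assert_array_equal(a.profiles, b.profiles)


class TestSimulateCatalog:
    def test_flat_exposures_spread_counts(self, six_signatures):
        counts, _ = simulate_catalog(six_signatures, [0, 0, 1, 0, 0, 0], 9600, seed=1)
        assert counts.sum() == 9600
        # each channel ~Binomial(9600, 1/96): mean 100, sd ~10
        assert np.all(np.abs(counts - 100) < 5 * 10)

    def test_zero_mutations(self, six_signatures):
        counts, _ = simulate_catalog(six_signatures, [1, 0, 0, 0, 0, 0], 0, seed=1)
        assert not counts.any()

    def test_deterministic(self, six_signatures):
        a, _ = simulate_catalog(six_signatures, [0.5, 0.5, 0, 0, 0, 0], 500, seed=9)
        b, _ = simulate_catalog(six_signatures, [0.5, 0.5, 0, 0, 0, 0], 500, seed=9)
        np.testing.assert_array_equal(a, b)


class TestSimulateVariants:
    def test_zero_noise_end_to_end_identity(self, small_reference, six_signatures):
        counts, _ = simulate_catalog(six_signatures, [0.25, 0.25, 0.25, 0.25, 0, 0], 600, seed=2)
        sim = simulate_variants(counts, small_reference, sample_id="s", seed=3)
        kept, _ = filter_variants(sim.records)
        kept = subtract_parental(kept, sim.parental)
        cat, _ = build_catalog(kept, small_reference, sample_ids=["s"])
        np.testing.assert_array_equal(cat.counts[0], counts)
        assert sim.n_expected_survivors == 600

    def test_all_parental_removes_everything(self, small_reference, six_signatures):
        counts, _ = simulate_catalog(six_signatures, [1, 0, 0, 0, 0, 0], 100, seed=4)
        sim = simulate_variants(
            counts, small_reference, sample_id="s", parental_fraction=1.0, seed=5
        )
        kept, _ = filter_variants(sim.records)
        assert subtract_parental(kept, sim.parental) == []
        assert sim.n_expected_survivors == 0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_truth_table_matches_filter_pipeline(self, small_reference, six_signatures, seed):
        counts, _ = simulate_catalog(six_signatures, [0.4, 0.3, 0.3, 0, 0, 0], 400, seed=seed)
        sim = simulate_variants(
            counts, small_reference, sample_id="s",
            contamination_fraction=0.2, parental_fraction=0.1, nonpass_fraction=0.1,
            seed=seed + 100,
        )
        kept, _ = filter_variants(sim.records)
        kept = subtract_parental(kept, sim.parental)
        assert len(kept) == sim.n_expected_survivors == sim.truth["survives"].sum()
        cat, _ = build_catalog(kept, small_reference, sample_ids=["s"])
        np.testing.assert_array_equal(cat.counts[0], sim.surviving_counts)

    def test_both_strands_exercised(self, small_reference, six_signatures):
        counts, _ = simulate_catalog(six_signatures, [1, 0, 0, 0, 0, 0], 300, seed=6)
        sim = simulate_variants(counts, small_reference, sample_id="s", seed=7)
        assert set(sim.truth["strand"]) == {"+", "-"}
        # minus-strand placements carry purine reference alleles
        minus = sim.truth[sim.truth["strand"] == "-"]
        assert set(minus["ref"]) <= {"A", "G"}

    def test_reference_too_short_raises(self, six_signatures):
        ref = make_reference(length=1000, seed=8)
        row = np.zeros(96)
        row[0] = 500  # cannot host 500 ACA sites in 1 kb
        with pytest.raises(ValueError, match="reference too short"):
            simulate_variants(row, ref, seed=9)


class TestControls:
    def test_row_totals_as_configured(self):
        probs = make_signatures(["flat"]).profiles[:, 0]
        cat = simulate_controls(probs, totals=[800, 1000, 1200], seed=1)
        np.testing.assert_array_equal(cat.totals(), [800, 1000, 1200])
        assert cat.sample_ids == ["control_1", "control_2", "control_3"]

    def test_degenerate_background(self):
        probs = np.zeros(96)
        probs[42] = 1.0
        cat = simulate_controls(probs, totals=[500], seed=2)
        assert cat.counts[0, 42] == 500


class TestCohortGenerator:
    def test_group_sizes_and_labels(self):
        cohort = simulate_cohort(CohortConfig(n_wt=30, n_mut=20, seed=1))
        statuses = [s.genotype["UBR5"] for s in cohort]
        assert statuses.count("wt") == 30 and statuses.count("mut") == 20
        assert len({s.sample_id for s in cohort}) == 50

    def test_effect_shifts_mut_group_mean(self):
        cohort = simulate_cohort(CohortConfig(effect=0.2, seed=2))
        wt = [s.activities["SBS13"] / s.total_mutations
              for s in cohort if s.genotype["UBR5"] == "wt"]
        mut = [s.activities["SBS13"] / s.total_mutations
               for s in cohort if s.genotype["UBR5"] == "mut"]
        assert np.mean(mut) - np.mean(wt) == pytest.approx(0.2, abs=0.05)

    def test_deterministic(self):
        a = simulate_cohort(CohortConfig(seed=3))
        b = simulate_cohort(CohortConfig(seed=3))
        assert [s.activities for s in a] == [s.activities for s in b]
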