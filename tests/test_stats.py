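"""Clopper-Pearson bounds, RMNE and likelihood statistics."""
import math

import pytest
from scipy.stats import binom

import mtmixgraph as mg
from mtmixgraph.stats import HaplotypeDatabase, consistent_records

from conftest import decode, make_reference


def cp_upper_bisect(successes, trials, confidence=0.95, tol=1e-12):
    """Independent oracle: invert P(X <= successes | p) = alpha/2 by
    bisection on the binomial tail."""
    alpha = 1 - confidence
    if successes >= trials:
        return 1.0
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if binom.cdf(successes, trials, mid) > alpha / 2:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestClopperPearson:
    @pytest.mark.parametrize("n", [1, 10, 100, 10_000])
    def test_zero_successes_closed_form(self, n):
        assert mg.clopper_pearson_upper(0, n) == pytest.approx(
            1 - 0.025 ** (1 / n), abs=1e-10
        )

    def test_all_successes_is_one(self):
        assert mg.clopper_pearson_upper(10, 10) == 1.0

    @pytest.mark.parametrize(
        "successes,trials", [(5, 10), (1, 20), (3, 7), (42, 100), (0, 3)]
    )
    def test_matches_tail_inversion_oracle(self, successes, trials):
        assert mg.clopper_pearson_upper(successes, trials) == pytest.approx(
            cp_upper_bisect(successes, trials), abs=1e-9
        )

    def test_bound_above_point_estimate(self):
        for s, t in [(0, 5), (2, 5), (5, 5), (10, 1000)]:
            assert mg.clopper_pearson_upper(s, t) >= s / t

    def test_monotone_nonincreasing_in_n_at_fixed_proportion(self):
        values = [mg.clopper_pearson_upper(n // 10, n) for n in (10, 100, 1000, 10000)]
        assert values == sorted(values, reverse=True)

    def test_zero_trials_undefined(self):
        with pytest.raises(ValueError):
            mg.clopper_pearson_upper(0, 0)


@pytest.fixture
def toy_setup(worked_ref):
    """A 4-record database around the 73G 154W 178M mixture: the two
    generating haplotypes plus two haplotypes excluded by private variants."""
    entries = [
        ("S1", "EU", "73G 154T 178A"),
        ("S2", "EU", "73G 154A 178C"),
        ("S3", "EU", "73G 154T 178A 12G" if worked_ref.base_at(12) != "G" else "73G 154T 178A 12C"),
        ("S4", "EU", "9G" if worked_ref.base_at(9) != "G" else "9C"),
    ]
    db = HaplotypeDatabase.build(worked_ref, entries)
    vg = mg.build_mixture_graph(mg.parse_variant_string("73G 154W 178M", worked_ref))
    return vg, db


class TestRmne:
    def test_toy_two_thirds(self, worked_ref):
        entries = [
            ("S1", "EU", "73G 154T 178A"),
            ("S2", "EU", "73G 154A 178C"),
            ("S3", "EU", "9G" if worked_ref.base_at(9) != "G" else "9C"),
        ]
        db = HaplotypeDatabase.build(worked_ref, entries)
        vg = mg.build_mixture_graph(
            mg.parse_variant_string("73G 154W 178M", worked_ref)
        )
        res = mg.rmne(vg, db)
        assert (res.n_consistent, res.n) == (2, 3)
        assert res.p_rmne == pytest.approx(2 / 3)
        assert set(res.consistent_ids) == {"S1", "S2"}

    def test_zero_consistent_closed_form_bound(self, worked_ref):
        entries = [(f"S{i}", "EU", "9G" if worked_ref.base_at(9) != "G" else "9C")
                   for i in range(5)]
        db = HaplotypeDatabase.build(worked_ref, entries)
        vg = mg.build_mixture_graph(mg.parse_variant_string("73G", worked_ref))
        res = mg.rmne(vg, db)
        assert res.p_rmne == 0.0
        assert res.p_rmne_upper == pytest.approx(1 - 0.025 ** (1 / 5))

    def test_everyone_matches_single_source(self, worked_ref):
        entries = [(f"S{i}", "EU", "73G") for i in range(4)]
        db = HaplotypeDatabase.build(worked_ref, entries)
        vg = mg.build_mixture_graph(mg.parse_variant_string("73G", worked_ref))
        res = mg.rmne(vg, db)
        assert res.p_rmne == 1.0 and res.p_rmne_upper == 1.0

    def test_missing_population_lists_available(self, toy_setup):
        vg, db = toy_setup
        with pytest.raises(mg.MtMixError, match="EU"):
            mg.rmne(vg, db, population="AF")

    def test_mask_collapses_discrimination(self, worked_ref):
        entries = [("S1", "EU", "73G 154T"), ("S2", "EU", "9G" if worked_ref.base_at(9) != "G" else "9C")]
        db = HaplotypeDatabase.build(worked_ref, entries)
        mask = mg.MaskIntervalSet.from_pairs([(1, worked_ref.length)])
        profile = mg.mask_profile(
            mg.parse_variant_string("73G 154W", worked_ref), mask
        )
        vg = mg.build_mixture_graph(profile)
        res = mg.rmne(vg, db, mask=mask)
        assert res.p_rmne == 1.0

    def test_prescreen_never_rejects_consistent_haplotypes(self):
        from mtmixgraph.simulate import PopulationModel, simulate_database, make_mixture

        model = PopulationModel(
            reference_length=200, n_haplotypes=60, indel_rate=0.01,
            substitution_rate=0.04, seed=17,
        )
        db = mg.simulate_database(model)
        compared = 0
        for i in range(0, 40, 2):
            merged = make_mixture(db.records[i], db.records[i + 1], db.reference)
            if isinstance(merged, mg.MixtureRejection):
                continue
            vg = mg.build_mixture_graph(merged)
            with_screen = {r.sample_id for r in consistent_records(vg, db, prescreen=True)}
            without = {r.sample_id for r in consistent_records(vg, db, prescreen=False)}
            assert with_screen == without
            compared += 1
        assert compared >= 10


class TestNaiveLikelihood:
    def test_single_unknown_is_its_frequency(self):
        assert mg.naive_likelihood([0.3]) == pytest.approx(0.3)

    def test_two_unknowns(self):
        assert mg.naive_likelihood([0.1, 0.2]) == pytest.approx(0.04)

    def test_three_unknowns(self):
        assert mg.naive_likelihood([0.5, 0.5, 0.5]) == pytest.approx(0.75)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            mg.naive_likelihood([1.2])


class TestTotalLikelihood:
    def test_single_explaining_pair(self, toy_setup):
        vg, db = toy_setup
        res = mg.total_likelihood(vg, db, u=2)
        assert res.n_explaining_sets == 1
        assert res.likelihood == pytest.approx(2 * 0.25 * 0.25)
        assert not res.empty_t

    def test_one_known_one_unknown(self, toy_setup, worked_ref):
        vg, db = toy_setup
        known = decode(worked_ref, "73G 154T 178A")
        res = mg.total_likelihood(vg, db, u=1, knowns=[known])
        assert res.likelihood == pytest.approx(0.25)

    def test_contributors_absent_gives_empty_t(self, worked_ref):
        entries = [("S1", "EU", "9G" if worked_ref.base_at(9) != "G" else "9C")]
        db = HaplotypeDatabase.build(worked_ref, entries)
        vg = mg.build_mixture_graph(
            mg.parse_variant_string("73G 154W 178M", worked_ref)
        )
        res = mg.total_likelihood(vg, db, u=2)
        assert res.likelihood == 0.0 and res.empty_t


class TestGbcLikelihood:
    def test_denominator_n_choose_2(self, toy_setup):
        vg, db = toy_setup
        res = mg.gbc_likelihood(vg, db, u=2)
        assert res.denominator == 4 * 3 // 2

    def test_exactly_generating_pair_explains(self, toy_setup):
        vg, db = toy_setup
        res = mg.gbc_likelihood(vg, db, u=2)
        assert res.n_explaining == 1
        assert res.proportion == pytest.approx(1 / 6)
        assert res.upper_bound >= res.proportion

    def test_no_explaining_combination(self, worked_ref):
        entries = [(f"S{i}", "EU", "9G" if worked_ref.base_at(9) != "G" else "9C")
                   for i in range(4)]
        db = HaplotypeDatabase.build(worked_ref, entries)
        vg = mg.build_mixture_graph(
            mg.parse_variant_string("73G 154W 178M", worked_ref)
        )
        res = mg.gbc_likelihood(vg, db, u=2)
        assert res.proportion == 0.0
        assert res.upper_bound == pytest.approx(
            mg.clopper_pearson_upper(0, math.comb(4, 2))
        )

    def test_with_replacement_denominator(self, toy_setup):
        vg, db = toy_setup
        res = mg.gbc_likelihood(vg, db, u=2, with_replacement=True)
        assert res.denominator == math.comb(4 + 1, 2)

    def test_u_larger_than_database_rejected(self, toy_setup):
        vg, db = toy_setup
        with pytest.raises(ValueError):
            mg.gbc_likelihood(vg, db, u=5)

    def test_zero_iff_total_likelihood_zero(self, toy_setup, worked_ref):
        vg, db = toy_setup
        gbc = mg.gbc_likelihood(vg, db, u=2)
        tot = mg.total_likelihood(vg, db, u=2)
        assert (gbc.proportion == 0) == (tot.likelihood == 0)


class TestDatabaseIO:
    def test_tsv_roundtrip(self, toy_setup, tmp_path):
        _, db = toy_setup
        path = tmp_path / "db.tsv"
        db.to_tsv(path)
        db2 = HaplotypeDatabase.from_tsv(path, db.reference)
        assert [r.sequence for r in db2.records] == [r.sequence for r in db.records]
        assert [r.calls for r in db2.records] == [r.calls for r in db.records]

    def test_duplicate_ids_rejected(self, worked_ref):
        with pytest.raises(ValueError):
            HaplotypeDatabase.build(
                worked_ref, [("S1", "EU", "73G"), ("S1", "EU", "")]
            )

    def test_single_source_rmne_equals_database_frequency(self, worked_ref):
        entries = [("S1", "EU", "73G"), ("S2", "EU", "73G"),
                   ("S3", "EU", "9G" if worked_ref.base_at(9) != "G" else "9C")]
        db = HaplotypeDatabase.build(worked_ref, entries)
        vg = mg.build_mixture_graph(mg.parse_variant_string("73G", worked_ref))
        res = mg.rmne(vg, db)
        assert res.p_rmne == pytest.approx(2 / 3)
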