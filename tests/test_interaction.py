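"""Pairwise stratum counting, E111 baselines and the omega measure."""

import math
from itertools import combinations

import pytest

from conftest import identity_norm, pooled, target_query
from dystosignal import synth
from dystosignal.dedup import dedup_bundles
from dystosignal.case_mapping import flag_cases, normalize_drugs
from dystosignal.interaction import (
    TripletSignal, count_triplets, expected_e111, omega_stat,
    screen_interactions,
)


class TestCountTriplets:
    def test_hand_enumerable_strata(self):
        # reports: {A,B,event} x2, {A}, {B,event}
        exposure = {"1": {"A", "B"}, "2": {"A", "B"}, "3": {"A"}, "4": {"B"}}
        cases = {"1", "2", "4"}
        out = count_triplets({"1", "2", "3", "4"}, exposure, cases)
        assert len(out) == 1
        t = out[0]
        assert (t.drugA, t.drugB) == ("A", "B")
        assert t.n111 == 2 and t.n11plus == 2
        assert t.f10 == 0.0 and t.f01 == 1.0 and t.f00 is None  # no neither-stratum

    def test_pair_without_event_coreports_absent(self):
        exposure = {"1": {"A"}, "2": {"B"}, "3": {"A", "B"}}
        out = count_triplets({"1", "2", "3"}, exposure, set(), min_n111=1)
        assert out == []

    def test_min_n111_threshold(self):
        exposure = {"1": {"A", "B"}}
        assert count_triplets({"1"}, exposure, {"1"}, min_n111=2) == []
        with pytest.raises(ValueError):
            count_triplets({"1"}, exposure, {"1"}, min_n111=0)

    def test_counts_match_brute_force_triple_loop(self, medium_sim,
                                                  medium_retained):
        """Strata for every pair equal an enumeration over (report, pair)
        that classifies each report into exactly one stratum."""
        config, bundles, ledger = medium_sim
        result, _ = medium_retained
        _, reac, drugs, _ = pooled(bundles)
        retained = sorted(result.retained_primaryids)[:5000]
        retained = set(retained)
        cases = flag_cases(reac, retained, target_query(config))
        exposure = normalize_drugs(drugs, identity_norm(config),
                                   roles={"PS", "SS"}, retained=retained)
        out = count_triplets(retained, exposure, cases, min_n111=1)
        by_pair = {(t.drugA, t.drugB): t for t in out}

        names = sorted(d.name for d in config.drug_catalog)
        for pair in combinations(names, 2):
            strata = {"both": [0, 0], "aonly": [0, 0],
                      "bonly": [0, 0], "neither": [0, 0]}
            for pid in retained:
                on = exposure.get(pid, set())
                key = {(True, True): "both", (True, False): "aonly",
                       (False, True): "bonly", (False, False): "neither"}[
                       (pair[0] in on, pair[1] in on)]
                strata[key][0] += 1
                strata[key][1] += pid in cases
            if strata["both"][1] == 0:
                assert pair not in by_pair
                continue
            t = by_pair[pair]
            assert t.n111 == strata["both"][1]
            assert t.n11plus == strata["both"][0]
            for f, key in [(t.f10, "aonly"), (t.f01, "bonly"),
                           (t.f00, "neither")]:
                n, ev = strata[key]
                assert f == (ev / n if n else None)


class TestExpectedE111:
    def triplet(self, f10, f01, f00, n11plus=100, n111=10):
        return TripletSignal("A", "B", n111, n11plus, f10, f01, f00)

    @pytest.mark.parametrize("model", ["odds_additive", "multiplicative",
                                       "max_single", "odds_multiplicative"])
    def test_equal_strata_give_background_rate(self, model):
        # no single-drug effect: every baseline predicts the shared rate
        t = self.triplet(0.1, 0.1, 0.1)
        assert expected_e111(t, model) == pytest.approx(10.0)
        assert t.model_used == model

    def test_odds_additive_hand_example(self):
        t = self.triplet(0.2, 1 / 90, 1 / 90, n11plus=100)
        # odds = 0.25 + 1/89 - 1/89 = 0.25 -> g = 0.2 -> E = 20
        assert expected_e111(t, "odds_additive") == pytest.approx(20.0)

    def test_floor_prevents_negative_interaction_baseline(self):
        # f00 larger than either single stratum: additive odds would dip
        # below the single-drug odds; the floor pins it there
        t = self.triplet(0.10, 0.10, 0.15, n11plus=100)
        e = expected_e111(t, "odds_additive")
        assert e == pytest.approx(100 * 0.10, abs=1e-9)

    def test_degenerate_stratum_falls_back(self):
        t = self.triplet(0.2, 1.0, 0.1)   # f01 = 1: infinite odds
        expected_e111(t, "odds_additive")
        assert t.model_used in ("multiplicative", "max_single")
        t2 = self.triplet(None, None, 0.1)
        expected_e111(t2, "odds_additive")
        assert t2.model_used == "background"
        assert t2.e111 == pytest.approx(0.1 * 100)  # f00 * n11plus

    def test_zero_coexposure_rejected(self):
        with pytest.raises(ValueError):
            expected_e111(self.triplet(0.1, 0.1, 0.1, n11plus=0))

    def test_matched_model_is_unbiased_under_null_interaction(self):
        """Single-drug effects present, interaction multiplier 1: with the
        generator-matched odds-multiplicative baseline, total E111 tracks
        total n111 across seeded replicates."""
        total_n111 = total_e111 = 0.0
        for seed in range(30):
            config = synth.SynthConfig(
                n_cases=2000,
                drug_catalog=[synth.DrugSpec("druga", 0.15),
                              synth.DrugSpec("drugb", 0.15),
                              synth.DrugSpec("filler", 0.5)],
                pt_catalog=[("dystonia", 0.05), ("nausea", 0.95)],
                target_event_pts=["dystonia"],
                signal_pairs={"druga": 4.0, "drugb": 4.0},
                interaction_triplets=[("druga", "drugb", 1.0)],
                duplicate_rate=0.0, deletion_rate=0.0, seed=seed,
            )
            bundles, ledger = synth.simulate(config)
            result, _ = dedup_bundles(bundles)
            retained = result.retained_primaryids
            _, reac, drugs, _ = pooled(bundles)
            cases = flag_cases(reac, retained, target_query(config))
            exposure = normalize_drugs(drugs, identity_norm(config),
                                       roles={"PS", "SS"}, retained=retained)
            for t in count_triplets(retained, exposure, cases):
                if {t.drugA, t.drugB} == {"druga", "drugb"}:
                    total_n111 += t.n111
                    total_e111 += expected_e111(t, "odds_multiplicative")
        assert total_n111 > 300
        assert abs(total_e111 - total_n111) / total_n111 < 0.15


class TestOmegaStat:
    def test_equal_observed_and_expected_gives_zero(self):
        omega, lo, hi = omega_stat(10, 10.0)
        assert omega == pytest.approx(0.0)
        assert lo < 0 < hi

    def test_interval_width_scales_inverse_sqrt(self):
        _, lo1, hi1 = omega_stat(25, 10.0)
        _, lo4, hi4 = omega_stat(100, 10.0)
        assert (hi1 - lo1) == pytest.approx(2 * (hi4 - lo4))
        assert (hi1 - lo1) == pytest.approx(2 * 1.96 / (math.log(2) * 5))

    def test_zero_count_leaves_bounds_undefined(self):
        omega, lo, hi = omega_stat(0, 3.0)
        assert omega == pytest.approx(math.log2(0.5 / 3.5))
        assert math.isnan(lo) and math.isnan(hi)

    def test_monotone_in_observed_and_expected(self):
        assert omega_stat(20, 5.0)[0] > omega_stat(10, 5.0)[0]
        assert omega_stat(10, 9.0)[0] > omega_stat(10, 20.0)[0]

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            omega_stat(-1, 5.0)


class TestScreenInteractions:
    def test_flag_requires_positive_lower_bound(self):
        t = TripletSignal("A", "B", 20, 40, 0.1, 0.1, 0.1)
        out = screen_interactions([t], model="max_single")
        assert len(out) == 1
        # n111=20 vs E111=4: strong excess
        assert out[0].flag and out[0].omega025 > 0

    def test_ranking_by_n111_then_omega(self):
        a = TripletSignal("A", "B", 49, 100, 0.1, 0.1, 0.1)
        b = TripletSignal("C", "D", 48, 100, 0.1, 0.1, 0.1)
        c = TripletSignal("E", "F", 49, 200, 0.1, 0.1, 0.1)
        ranked = screen_interactions([b, a, c])
        assert [t.n111 for t in ranked] == [49, 49, 48]
        assert ranked[0].omega >= ranked[1].omega

    def test_injected_interaction_detected(self, medium_sim, medium_retained):
        """The aripiprazole+risperidone triplet carries an excess odds
        multiplier of 3 in the generator and is flagged."""
        config, bundles, ledger = medium_sim
        result, _ = medium_retained
        retained = result.retained_primaryids
        _, reac, drugs, _ = pooled(bundles)
        cases = flag_cases(reac, retained, target_query(config))
        exposure = normalize_drugs(drugs, identity_norm(config),
                                   roles={"PS", "SS"}, retained=retained)
        triplets = count_triplets(retained, exposure, cases, min_n111=3)
        screened = screen_interactions(triplets, model="odds_multiplicative")
        pair = next(t for t in screened
                    if {t.drugA, t.drugB} == {"aripiprazole", "risperidone"})
        assert pair.flag

    def test_null_calibration_false_positive_rate(self):
        """All interaction multipliers 1: among pooled pair-triplets with
        n111 >= 20 under the matched baseline, at most 7.5% have
        omega025 > 0 (about the nominal 2.5% plus estimation slack)."""
        flagged = total = 0
        for seed in (101, 102, 103):
            catalog = [synth.DrugSpec(f"d{i:02d}", 0.25) for i in range(20)]
            config = synth.SynthConfig(
                n_cases=5000, drug_catalog=catalog,
                pt_catalog=[("dystonia", 0.15), ("nausea", 0.85)],
                target_event_pts=["dystonia"],
                duplicate_rate=0.0, deletion_rate=0.0, seed=seed,
            )
            bundles, _ = synth.simulate(config)
            result, _ = dedup_bundles(bundles)
            retained = result.retained_primaryids
            _, reac, drugs, _ = pooled(bundles)
            cases = flag_cases(reac, retained, target_query(config))
            exposure = normalize_drugs(drugs, identity_norm(config),
                                       roles={"PS", "SS"}, retained=retained)
            triplets = count_triplets(retained, exposure, cases, min_n111=20)
            for t in screen_interactions(triplets,
                                         model="odds_multiplicative"):
                total += 1
                flagged += t.flag
        assert total >= 400
        assert flagged / total <= 0.075

    def test_power_against_injected_excess(self):
        """Excess multiplier 5 on a frequently co-reported pair is flagged
        in at least 95 of 100 seeded replicates."""
        hits = 0
        for seed in range(100):
            config = synth.SynthConfig(
                n_cases=2500,
                drug_catalog=[synth.DrugSpec("druga", 0.2),
                              synth.DrugSpec("drugb", 0.2),
                              synth.DrugSpec("filler", 0.5)],
                pt_catalog=[("dystonia", 0.05), ("nausea", 0.95)],
                target_event_pts=["dystonia"],
                interaction_triplets=[("druga", "drugb", 5.0)],
                duplicate_rate=0.0, deletion_rate=0.0, seed=seed,
            )
            bundles, _ = synth.simulate(config)
            result, _ = dedup_bundles(bundles)
            retained = result.retained_primaryids
            _, reac, drugs, _ = pooled(bundles)
            cases = flag_cases(reac, retained, target_query(config))
            exposure = normalize_drugs(drugs, identity_norm(config),
                                       roles={"PS", "SS"}, retained=retained)
            triplets = count_triplets(retained, exposure, cases, min_n111=1)
            screened = screen_interactions(triplets,
                                           model="odds_multiplicative")
            pair = next((t for t in screened
                         if {t.drugA, t.drugB} == {"druga", "drugb"}), None)
            hits += bool(pair and pair.flag)
        assert hits >= 95
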