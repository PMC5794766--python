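import numpy as np
import pytest

from trigger_forge import bioassay as ba
from trigger_forge.synth import (
    BioassaySimSpec,
    RootTrialSimSpec,
    fourfold_series,
    mortality_at,
    simulate_diet_bioassay,
    simulate_root_trial,
)


class TestGrowthInhibition:
    def test_equal_per_insect_weight_gives_zero(self):
        assert ba.growth_inhibition(20, 10, 40, 20) == pytest.approx(0.0)

    def test_weightless_survivors_give_one(self):
        assert ba.growth_inhibition(0, 10, 40, 20) == pytest.approx(1.0)

    def test_worked_example(self):
        assert ba.growth_inhibition(10, 20, 30, 15) == pytest.approx(0.75)

    def test_negative_gi_allowed(self):
        assert ba.growth_inhibition(60, 10, 40, 20) < 0

    def test_control_collapse_is_error(self):
        with pytest.raises(ValueError):
            ba.growth_inhibition(10, 20, 0, 15)
        with pytest.raises(ValueError):
            ba.growth_inhibition(10, 0, 30, 15)

    def test_invariant_to_well_splitting(self):
        pooled_t = [ba.BioassayWell("t", 10, 16, 4, 9.0)]
        split_t = [ba.BioassayWell("t", 10, 8, 1, 5.0, "r1"),
                   ba.BioassayWell("t", 10, 8, 3, 4.0, "r2")]
        ctrl = [ba.BioassayWell("c", 0, 16, 0, 20.0)]
        assert ba.gi_from_wells(pooled_t, ctrl) == pytest.approx(
            ba.gi_from_wells(split_t, ctrl)
        )


def exact_wells(lc50, slope, doses, n=10000, c=0.0):
    """Deterministic wells whose pooled mortality equals the curve."""
    wells = []
    for d in doses:
        p = mortality_at(d, lc50, slope, c)
        wells.append(ba.BioassayWell("t", d, n, int(round(n * p)), float(n)))
    wells.append(ba.BioassayWell("c", 0.0, n, int(round(n * c)), float(n)))
    return wells


class TestFitDoseResponse:
    def test_noiseless_logistic_recovery(self):
        wells = exact_wells(10.0, 2.0, fourfold_series(160.0, 6))
        fit = ba.fit_dose_response(wells, "mortality", profile_ci=False)
        assert fit.converged
        assert fit.point == pytest.approx(10.0, rel=0.01)
        assert fit.control_rate == 0.0

    def test_dose_unit_rescaling_scales_lc50(self):
        wells = exact_wells(10.0, 2.0, fourfold_series(160.0, 6))
        scaled = [ba.BioassayWell(w.treatment, w.dose * 1000, w.n_start, w.n_dead,
                                  w.total_live_weight, w.replicate) for w in wells]
        f1 = ba.fit_dose_response(wells, "mortality", profile_ci=False)
        f2 = ba.fit_dose_response(scaled, "mortality", profile_ci=False)
        assert f2.point == pytest.approx(f1.point * 1000, rel=0.01)

    def test_abbott_floor_recovery_with_control_mortality(self):
        wells = exact_wells(10.0, 2.0, fourfold_series(160.0, 6), c=0.10)
        fit = ba.fit_dose_response(wells, "mortality", profile_ci=False)
        assert fit.control_rate == pytest.approx(0.10, abs=0.001)
        assert fit.point == pytest.approx(10.0, rel=0.02)

    def test_profile_ci_brackets_point(self):
        wells = simulate_diet_bioassay(BioassaySimSpec(true_lc50=20.0), seed=5)
        fit = ba.fit_dose_response(wells, "mortality")
        assert fit.converged
        assert fit.ci_low < fit.point < fit.ci_high

    def test_matches_statsmodels_glm_without_floor(self):
        import statsmodels.api as sm

        wells = simulate_diet_bioassay(
            BioassaySimSpec(true_lc50=20.0, control_mortality=0.0), seed=6
        )
        fit = ba.fit_dose_response(wells, "mortality", abbott=False, profile_ci=False)
        treated = [w for w in wells if w.dose > 0]
        import pandas as pd

        tab = pd.DataFrame({"dose": [w.dose for w in treated],
                            "dead": [w.n_dead for w in treated],
                            "n": [w.n_start for w in treated]}).groupby("dose").sum()
        X = sm.add_constant(np.log10(tab.index.to_numpy()))
        y = np.column_stack([tab.dead, tab.n - tab.dead])
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        lc50_glm = 10 ** (-res.params[0] / res.params[1])
        assert fit.point == pytest.approx(lc50_glm, rel=1e-3)

    def test_fewer_than_four_doses_is_error(self):
        wells = exact_wells(10.0, 2.0, (5.0, 20.0, 80.0))
        with pytest.raises(ValueError, match="4 distinct"):
            ba.fit_dose_response(wells, "mortality")

    def test_all_alive_flagged_not_converged(self):
        wells = [ba.BioassayWell("t", d, 16, 0, 16.0) for d in (1, 4, 16, 64)]
        fit = ba.fit_dose_response(wells, "mortality")
        assert not fit.converged and fit.point is None

    def test_gi50_recovery(self):
        spec = BioassaySimSpec(true_lc50=50.0, n_per_dose=32)
        wells = simulate_diet_bioassay(spec, seed=7)
        fit = ba.fit_dose_response(wells, "GI", seed=1, n_boot=200)
        assert fit.converged
        # weight model gi50 default is 10 ng/cm2
        assert fit.point == pytest.approx(10.0, rel=0.5)
        if fit.ci_low is not None:
            assert fit.ci_low < fit.point < fit.ci_high

    def test_gi_bootstrap_requires_seed(self):
        wells = simulate_diet_bioassay(BioassaySimSpec(), seed=8)
        with pytest.raises(ValueError, match="seed"):
            ba.fit_dose_response(wells, "GI")


class TestPassFail:
    @pytest.mark.parametrize("nis,expected",
                             [(0.5, "pass"), (0.51, "fail"), (0.0, "pass"), (1.0, "fail")])
    def test_boundary(self, nis, expected):
        assert ba.pass_fail(ba.RootEvent("c", "e1", "d1", nis)) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ba.RootEvent("c", "e1", "d1", 1.2)


class TestConstructProportions:
    def test_binomial_proportion_and_sem(self):
        events = [ba.RootEvent("hp", f"e{i}", "d1", 0.1 if i < 20 else 0.9)
                  for i in range(21)]
        res = ba.construct_proportions(events)
        row = res.proportions.iloc[0]
        assert row.proportion == pytest.approx(20 / 21)
        assert row["sem"] == pytest.approx(np.sqrt((20 / 21) * (1 / 21) / 21), abs=1e-6)

    def test_all_pass_separation_warns_without_model(self):
        events = [ba.RootEvent("hp", f"e{i}", f"d{i % 2}", 0.1) for i in range(10)]
        res = ba.construct_proportions(events)
        assert res.model_params is None
        assert any("separation" in w for w in res.warnings)

    def test_model_recovers_probabilities_without_date_effect(self):
        spec = RootTrialSimSpec(
            constructs=(("good", 0.85), ("bad", 0.35)),
            events_per_construct=120,
            test_dates=(("d1", 0.0), ("d2", 0.0)),
        )
        events = simulate_root_trial(spec, seed=3)
        res = ba.construct_proportions(events)
        props = res.proportions.set_index("construct")
        assert abs(props.loc["good", "proportion"] - 0.85) < 0.09
        assert abs(props.loc["bad", "proportion"] - 0.35) < 0.10
        assert res.model_proportions is not None
        for con in ("good", "bad"):
            assert res.model_proportions[con] == pytest.approx(
                props.loc[con, "proportion"], abs=0.02
            )

    def test_empirical_pass_rate_converges(self):
        spec = RootTrialSimSpec(constructs=(("hp", 0.7),), events_per_construct=1000)
        events = simulate_root_trial(spec, seed=4)
        frac = np.mean([ba.pass_fail(e) == "pass" for e in events])
        se = np.sqrt(0.7 * 0.3 / 1000)
        assert abs(frac - 0.7) <= 3 * se


class TestPfaffl:
    def _meas(self, gene, eff, treated, control):
        return ba.QpcrMeasurement(gene, eff, tuple(treated), tuple(control))

    def test_no_shift_gives_unit_ratio(self):
        t = self._meas("t", 2.0, [20, 20], [20, 20])
        r = self._meas("r", 2.0, [18, 18], [18, 18])
        res = ba.pfaffl_ratio(t, r)
        assert res.ratio == pytest.approx(1.0)
        assert res.knockdown_pct == pytest.approx(0.0)

    def test_closed_form_example(self):
        t = self._meas("t", 2.0, [23.0, 23.0], [20.0, 20.0])  # dCt = -3
        r = self._meas("r", 2.0, [18.0, 18.0], [18.0, 18.0])
        res = ba.pfaffl_ratio(t, r)
        assert res.ratio == pytest.approx(0.125)
        assert res.knockdown_pct == pytest.approx(87.5)

    def test_swapping_genes_inverts_ratio(self):
        t = self._meas("t", 1.9, [22.5, 22.7], [20.1, 20.0])
        r = self._meas("r", 2.0, [18.2, 18.1], [18.0, 18.3])
        assert ba.pfaffl_ratio(t, r).ratio == pytest.approx(
            1.0 / ba.pfaffl_ratio(r, t).ratio
        )

    def test_textbook_ddct_when_efficiency_two(self):
        t = self._meas("t", 2.0, [24.0, 24.2], [21.0, 21.2])
        r = self._meas("r", 2.0, [19.0, 19.1], [18.9, 19.0])
        res = ba.pfaffl_ratio(t, r)
        ddct = (np.mean([24.0, 24.2]) - np.mean([21.0, 21.2])) - (
            np.mean([19.0, 19.1]) - np.mean([18.9, 19.0])
        )
        assert res.ratio == pytest.approx(2.0 ** -ddct)

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError):
            ba.QpcrMeasurement("t", 0.9, (20.0,), (20.0,))


class TestMortalitySummary:
    def test_uniform_replicates(self):
        wells = [ba.BioassayWell("t", 10, 10, 10, 0.0, f"r{i}") for i in range(3)]
        out = ba.mortality_summary(wells)
        assert out.mean_pct.iloc[0] == pytest.approx(100.0)
        assert out["sem"].iloc[0] == pytest.approx(0.0)

    def test_worked_example(self):
        deads = [9, 10, 10]
        wells = [ba.BioassayWell("t", 10, 10, d, 10.0 - d, f"r{i}")
                 for i, d in enumerate(deads)]
        out = ba.mortality_summary(wells)
        assert out.mean_pct.iloc[0] == pytest.approx(96.67, abs=0.01)
        assert out["sem"].iloc[0] == pytest.approx(3.33, abs=0.01)

    def test_single_replicate_sem_is_na(self):
        out = ba.mortality_summary([ba.BioassayWell("t", 10, 10, 5, 5.0)])
        assert np.isnan(out["sem"].iloc[0])
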