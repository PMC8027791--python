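import json

import numpy as np
import pandas as pd
import pytest

from assrpipe.simulate import simulate_feature_table
from assrpipe.stats import (
    DoseModelSpec,
    analyze_measures,
    build_design,
    fit_dose_model,
    summarize_results,
    write_results,
)


def make_table(rng, **kwargs):
    return simulate_feature_table(10, rng, **kwargs)


class TestBuildDesign:
    def test_eeg_measure_uses_hours_one_to_four(self, rng):
        tab = simulate_feature_table(
            4, rng, timepoints=("h1", "h2", "h3", "h4", "h5")
        )
        spec = DoseModelSpec("assr40_itpc")
        out = build_design(tab, spec)
        assert set(out["timepoint"].astype(str)) == {"h1", "h2", "h3", "h4"}

    def test_metabolite_measure_keeps_five_hours(self, rng):
        tab = simulate_feature_table(
            4, rng, measure="KYNA", grand_mean=6.0, sd_subject=1.0,
            sd_resid=0.5, timepoints=("h1", "h2", "h3", "h4", "h5"),
            dose_effects={"placebo": 0.0, "low": 2.0, "high": 4.0},
        )
        out = build_design(tab, DoseModelSpec("KYNA"))
        assert set(out["timepoint"].astype(str)) == {"h1", "h2", "h3", "h4", "h5"}

    def test_baseline_rows_never_become_responses(self, rng):
        out = build_design(make_table(rng), DoseModelSpec("assr40_itpc"))
        assert (out["timepoint"].astype(str) != "baseline").all()

    def test_absent_measure_rejected(self, rng):
        with pytest.raises(ValueError, match="absent"):
            build_design(make_table(rng), DoseModelSpec("nope"))

    def test_missing_dose_condition_warns(self, rng):
        tab = make_table(rng)
        tab = tab[~((tab.subject_id == "S01") & (tab.dose == "high"))]
        with pytest.warns(UserWarning, match="S01"):
            build_design(tab, DoseModelSpec("assr40_itpc"))


class TestFitDoseModel:
    def test_high_dose_only_effect_recovered(self, rng):
        """Injected high-dose effect yields a positive high-vs-placebo
        contrast with the low-vs-placebo contrast near zero."""
        tab = make_table(rng)  # default: high-only effect of 0.02
        spec = DoseModelSpec("assr40_itpc")
        res = fit_dose_model(build_design(tab, spec), spec)
        assert res.contrasts["high"].estimate > 0
        assert res.contrasts["high"].p < 0.05
        assert abs(res.contrasts["low"].estimate) < res.contrasts["high"].estimate
        assert res.contrasts["high"].ci_low < res.contrasts["high"].estimate
        assert res.contrasts["high"].ci_low > 0

    def test_relabeling_doses_flips_contrast_sign(self, rng):
        tab = make_table(rng)
        spec = DoseModelSpec("assr40_itpc")
        res = fit_dose_model(build_design(tab, spec), spec)
        swapped = tab.copy()
        swapped["dose"] = swapped["dose"].map(
            {"placebo": "high", "high": "placebo", "low": "low"}
        )
        res2 = fit_dose_model(build_design(swapped, spec), spec)
        assert res2.contrasts["high"].estimate == pytest.approx(
            -res.contrasts["high"].estimate, rel=1e-4
        )

    def test_row_order_invariance(self, rng):
        tab = make_table(rng)
        spec = DoseModelSpec("assr40_itpc")
        a = fit_dose_model(build_design(tab, spec), spec)
        shuffled = tab.sample(frac=1.0, random_state=1)
        b = fit_dose_model(build_design(shuffled, spec), spec)
        assert a.F_dose == pytest.approx(b.F_dose, rel=1e-5)

    def test_too_few_subjects_rejected(self, rng):
        tab = simulate_feature_table(2, rng)
        spec = DoseModelSpec("assr40_itpc")
        with pytest.raises(ValueError, match="3 subjects"):
            fit_dose_model(build_design(tab, spec), spec)

    def test_zero_variance_rejected(self, rng):
        tab = make_table(rng)
        tab["value"] = 1.0
        spec = DoseModelSpec("assr40_itpc")
        with pytest.raises(ValueError, match="variance"):
            fit_dose_model(build_design(tab, spec), spec)


class TestProfiledREML:
    def test_matches_statsmodels_mixedlm(self, rng):
        """Independent cross-check: the profiled-REML fitter reproduces
        statsmodels MixedLM fixed effects and variance components on a
        well-conditioned problem."""
        import warnings

        import statsmodels.formula.api as smf

        from assrpipe.stats import profile_reml_fit

        # a fixture where the reference optimizer itself converges
        tab = build_design(make_table(np.random.default_rng(42)),
                           DoseModelSpec("assr40_itpc"))
        formula = (
            "value ~ C(dose, Treatment('placebo')) + C(timepoint) "
            "+ baseline_value"
        )
        mine = profile_reml_fit(formula, tab, tab["subject_id"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = smf.mixedlm(formula, data=tab,
                              groups=tab["subject_id"]).fit(reml=True,
                                                            method="lbfgs")
        assert np.abs(mine.fe_params - ref.fe_params).max() < 1e-5
        assert mine.sigma2 == pytest.approx(ref.scale, rel=1e-4)
        assert mine.tau2 == pytest.approx(float(ref.cov_re.iloc[0, 0]),
                                          rel=1e-3)

    def test_zero_group_variance_degrades_to_ols(self, rng):
        """With no subject effect the variance ratio collapses to ~0 and
        the fit matches ordinary least squares."""
        import statsmodels.formula.api as smf

        from assrpipe.stats import profile_reml_fit

        tab = build_design(
            simulate_feature_table(10, rng, sd_subject=0.0),
            DoseModelSpec("assr40_itpc"),
        )
        formula = "value ~ C(dose, Treatment('placebo')) + C(timepoint)"
        mine = profile_reml_fit(formula, tab, tab["subject_id"])
        ols = smf.ols(formula, data=tab).fit()
        assert mine.tau2 < 0.2 * mine.sigma2
        assert np.abs(mine.fe_params - ols.params).max() < 2e-3


class TestSummary:
    def test_one_row_per_measure_and_round_trip(self, rng, tmp_path):
        tabs = pd.concat([
            make_table(rng),
            simulate_feature_table(
                10, rng, measure="KYNA", grand_mean=6.0, sd_subject=1.0,
                sd_resid=0.5,
                dose_effects={"placebo": 0.0, "low": 2.0, "high": 4.0},
                timepoints=("h1", "h2", "h3", "h4", "h5"),
            ),
        ])
        results = analyze_measures(tabs)
        summary = summarize_results(results)
        assert len(summary) == 2
        write_results(results, summary, tmp_path / "r.json", tmp_path / "r.csv")
        back_json = json.loads((tmp_path / "r.json").read_text())
        back_csv = pd.read_csv(tmp_path / "r.csv")
        assert len(back_json["results"]) == 2
        for row in summary.itertuples():
            jr = next(r for r in back_json["results"]
                      if r["measure"] == row.measure)
            cr = back_csv[back_csv.measure == row.measure].iloc[0]
            assert jr["F_dose"] == pytest.approx(row.F)
            assert cr["F"] == pytest.approx(row.F)

    def test_significance_flag_at_alpha(self, rng):
        tab = make_table(rng, dose_effects={"placebo": 0, "low": 0,
                                            "high": 0.1})
        results = analyze_measures(tab)
        summary = summarize_results(results, alpha=0.05)
        assert bool(summary["significant"].iloc[0]) == bool(
            summary["p"].iloc[0] < 0.05
        )

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            summarize_results([])
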