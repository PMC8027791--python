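"""Crossover dose-contrast statistics: linear mixed models per measure.

Each extracted measure is analyzed with a linear mixed model containing
dose condition (placebo reference) as a fixed effect, a random intercept
per subject, and time plus the pretreatment-baseline measurement as
covariates.  EEG measures use post-dose hours 1-4; plasma metabolites (and
any other hourly measure) use hours 1-5.  The model yields an omnibus dose
F-test and the two pairwise contrasts low-vs-placebo and high-vs-placebo
with t, p, and 95% confidence intervals.

Estimation is REML (ML optional) by profiling the likelihood down to the
single variance ratio tau^2/sigma^2 — with one random intercept the mixed
model admits a closed-form GLS solution at each ratio, so fitting is a
bounded 1-D minimization that cannot diverge.  Test degrees of freedom use
a between-within fallback (residual observations minus subjects minus
within-subject fixed-effect parameters), recorded in the result metadata.
The baseline covariate is centered within subject by default: it is a
re-measurement of the trait the random intercept models, and entering it
raw makes the covariate endogenous, inflating the size of the dose test
(verified by null simulation).  Measures are tested separately without
multiplicity correction by default; Benjamini-Hochberg is available as an
option.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sp_stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .design import DOSES, EEG_TIMEPOINTS, METABOLITE_TIMEPOINTS, PLACEBO

logger = logging.getLogger(__name__)

#: measures analyzed over h1-h4 (everything else defaults to h1-h5)
EEG_MEASURES = (
    "assr40_power", "assr40_itpc",
    "assr30_power", "assr30_itpc",
    "assr20_power", "assr20_itpc",
    "resting_gamma_db", "resting_slope",
)


@dataclass(frozen=True)
class DoseModelSpec:
    """Model specification for one measure."""

    measure: str
    timepoint_range: tuple[str, ...] | None = None  # inferred if None
    time_as_categorical: bool = True
    reml: bool = True
    #: how the pretreatment baseline enters: "within" centers it per subject
    #: (its between-subject part is the random intercept's job; entering it
    #: raw makes the covariate endogenous and inflates the dose test size),
    #: "raw" uses the plain session value
    baseline_centering: str = "within"

    @property
    def timepoints(self) -> tuple[str, ...]:
        if self.timepoint_range is not None:
            return self.timepoint_range
        if self.measure in EEG_MEASURES:
            return EEG_TIMEPOINTS
        return METABOLITE_TIMEPOINTS


@dataclass(frozen=True)
class Contrast:
    """One dose-vs-placebo contrast."""

    dose: str
    estimate: float
    se: float
    t: float
    p: float
    ci_low: float
    ci_high: float


@dataclass
class DoseModelResult:
    """Fitted crossover model summary for one measure."""

    measure: str
    F_dose: float
    p_dose: float
    df_num: int
    df_den: int
    adjusted_means: dict[str, tuple[float, float]]  # dose -> (mean, se)
    contrasts: dict[str, Contrast]  # "low", "high"
    n_subjects: int
    n_rows: int
    converged: bool
    df_method: str = "between-within"

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "F_dose": self.F_dose,
            "p_dose": self.p_dose,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "adjusted_means": {
                d: {"mean": m, "se": s} for d, (m, s) in self.adjusted_means.items()
            },
            "contrasts": {d: vars(c) for d, c in self.contrasts.items()},
            "n_subjects": self.n_subjects,
            "n_rows": self.n_rows,
            "converged": self.converged,
            "df_method": self.df_method,
        }


def build_design(rows: pd.DataFrame, spec: DoseModelSpec) -> pd.DataFrame:
    """Filter a feature table to one measure's model-ready response table.

    Keeps only the spec's post-dose timepoints (baseline rows enter solely
    through the ``baseline_value`` covariate); drops out-of-range
    timepoints with a logged count; encodes dose with placebo as reference.
    """
    df = rows[rows["measure"] == spec.measure].copy()
    if df.empty:
        raise ValueError(f"measure {spec.measure!r} absent from feature table")
    df = df[df["timepoint"] != "baseline"]
    in_range = df["timepoint"].isin(spec.timepoints)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d rows outside timepoints %s",
            spec.measure, n_dropped, spec.timepoints,
        )
    df = df[in_range]
    if df["baseline_value"].isna().any():
        raise ValueError(f"{spec.measure}: missing baseline_value covariates")
    # warn (not fail) when a subject misses a whole dose condition
    for subject, sub in df.groupby("subject_id"):
        missing = set(DOSES) - set(sub["dose"])
        if missing:
            warnings.warn(
                f"subject {subject} missing dose condition(s) {sorted(missing)}",
                stacklevel=2,
            )
    df["dose"] = pd.Categorical(df["dose"], categories=list(DOSES))
    # only levels actually observed: empty factor columns make X singular
    present = [t for t in spec.timepoints if t in set(df["timepoint"])]
    df["timepoint"] = pd.Categorical(df["timepoint"], categories=present)
    df["time_h"] = df["timepoint"].astype(str).str.removeprefix("h").astype(float)
    return df.reset_index(drop=True)


@dataclass
class MixedFit:
    """Profiled-REML fit of a random-intercept linear mixed model."""

    fe_params: pd.Series
    cov_params: pd.DataFrame
    sigma2: float  # residual variance
    tau2: float  # random-intercept variance
    converged: bool
    reml: bool
    loglike: float


def profile_reml_fit(
    formula: str,
    data: pd.DataFrame,
    groups: pd.Series,
    reml: bool = True,
    log_ratio_bounds: tuple[float, float] = (-12.0, 12.0),
    xatol: float = 1e-10,
) -> MixedFit:
    """Fit ``y = X b + Z u + e`` with one random intercept per group.

    For a single variance component the (RE)ML criterion profiles to a 1-D
    function of the variance ratio theta = tau^2/sigma^2: for each theta the
    fixed effects have a closed-form GLS solution (per-group block inverse
    (I + theta J)^-1 = I - theta/(1+theta n_g) J), so the fit reduces to a
    bounded scalar minimization over log(theta).  This is deterministic and
    cannot diverge, and on well-conditioned problems it agrees with general
    mixed-model software to optimizer precision.
    """
    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    yv = y.to_numpy().ravel()
    Xv = X.to_numpy()
    n, p = Xv.shape
    codes, _ = pd.factorize(groups, sort=True)
    group_index = [np.where(codes == g)[0] for g in range(codes.max() + 1)]
    sizes = np.array([len(ix) for ix in group_index])

    def gls(theta: float):
        # X'V0^-1 X, X'V0^-1 y, y'V0^-1 y and log|V0| for V0 = I + theta ZZ'
        xtvx = Xv.T @ Xv
        xtvy = Xv.T @ yv
        ytvy = yv @ yv
        logdet_v = 0.0
        for ix, n_g in zip(group_index, sizes):
            w = theta / (1.0 + theta * n_g)
            xs = Xv[ix].sum(axis=0)
            ys = yv[ix].sum()
            xtvx -= w * np.outer(xs, xs)
            xtvy -= w * xs * ys
            ytvy -= w * ys * ys
            logdet_v += np.log1p(theta * n_g)
        beta = np.linalg.solve(xtvx, xtvy)
        rss = ytvy - xtvy @ beta  # r' V0^-1 r
        return beta, xtvx, rss, logdet_v

    df_resid = (n - p) if reml else n

    def criterion(log_theta: float) -> float:
        beta, xtvx, rss, logdet_v = gls(np.exp(log_theta))
        sigma2 = max(rss / df_resid, 1e-300)
        value = df_resid * np.log(sigma2) + logdet_v
        if reml:
            value += np.linalg.slogdet(xtvx)[1]
        return value

    opt = minimize_scalar(
        criterion, bounds=log_ratio_bounds, method="bounded",
        options={"xatol": xatol},
    )
    # compare against the boundary theta = 0 (no group variance)
    theta = float(np.exp(opt.x))
    if opt.fun > criterion(-290.0):
        theta = 0.0
    beta, xtvx, rss, _ = gls(theta)
    sigma2 = rss / df_resid
    cov = sigma2 * np.linalg.inv(xtvx)
    names = list(X.columns)
    return MixedFit(
        fe_params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        sigma2=float(sigma2),
        tau2=float(theta * sigma2),
        converged=bool(opt.success),
        reml=reml,
        loglike=-0.5 * float(opt.fun),
    )


def fit_dose_model(table: pd.DataFrame, spec: DoseModelSpec) -> DoseModelResult:
    """Fit the crossover mixed model and extract omnibus test and contrasts.

    Random intercept per subject; fixed effects: dose (placebo reference),
    time (categorical by default), and the pretreatment-baseline value.
    Non-convergence raises, never passes silently.
    """
    n_subjects = table["subject_id"].nunique()
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    per_subject_doses = table.groupby("subject_id")["dose"].nunique()
    if (per_subject_doses < 2).all():
        raise ValueError("singular design: no subject has 2+ dose conditions")
    if np.isclose(table["value"].var(), 0.0):
        raise ValueError("zero response variance")

    time_term = "C(timepoint)" if spec.time_as_categorical else "time_h"
    formula = f"value ~ C(dose, Treatment('{PLACEBO}')) + {time_term}"
    table = table.copy()
    if spec.baseline_centering == "within":
        subject_mean = table.groupby("subject_id")["baseline_value"].transform(
            "mean"
        )
        table["baseline_c"] = table["baseline_value"] - subject_mean
    elif spec.baseline_centering == "raw":
        table["baseline_c"] = table["baseline_value"]
    else:
        raise ValueError(
            f"unknown baseline_centering {spec.baseline_centering!r}"
        )
    # a constant covariate (e.g. a drug-derived analyte absent pre-dose) is
    # inestimable; drop it rather than fit a singular design
    baseline_used = table["baseline_c"].std() > 0
    if baseline_used:
        formula += " + baseline_c"
    else:
        logger.info("%s: constant baseline covariate dropped", spec.measure)
    fit = profile_reml_fit(formula, table, table["subject_id"], reml=spec.reml)
    if not fit.converged:
        raise RuntimeError(f"{spec.measure}: mixed model did not converge")

    params = fit.fe_params
    cov = fit.cov_params
    dose_terms = {
        d: f"C(dose, Treatment('{PLACEBO}'))[T.{d}]" for d in ("low", "high")
    }
    # between-within denominator df: response rows minus subjects minus
    # within-subject fixed-effect parameters (all non-intercept terms here)
    p_within = len(params) - 1
    df_den = len(table) - n_subjects - p_within
    if df_den <= 0:
        raise ValueError("non-positive denominator degrees of freedom")

    contrasts: dict[str, Contrast] = {}
    tcrit = sp_stats.t.ppf(0.975, df_den)
    for dose, term in dose_terms.items():
        est = float(params[term])
        se = float(np.sqrt(cov.loc[term, term]))
        tval = est / se
        pval = 2.0 * sp_stats.t.sf(abs(tval), df_den)
        contrasts[dose] = Contrast(
            dose=dose, estimate=est, se=se, t=float(tval), p=float(pval),
            ci_low=est - tcrit * se, ci_high=est + tcrit * se,
        )

    # omnibus dose test: Wald chi2 on the two dose coefficients, scaled to F
    terms = list(dose_terms.values())
    b = params[terms].to_numpy()
    V = cov.loc[terms, terms].to_numpy()
    chi2 = float(b @ np.linalg.solve(V, b))
    F = chi2 / 2.0
    p_dose = float(sp_stats.f.sf(F, 2, df_den))

    # adjusted (marginal) means per dose at balanced time and mean baseline
    means = _adjusted_means(params, cov, table, spec)

    return DoseModelResult(
        measure=spec.measure,
        F_dose=F,
        p_dose=p_dose,
        df_num=2,
        df_den=int(df_den),
        adjusted_means=means,
        contrasts=contrasts,
        n_subjects=int(n_subjects),
        n_rows=int(len(table)),
        converged=bool(getattr(fit, "converged", True)),
    )


def _adjusted_means(params, cov, table, spec) -> dict[str, tuple[float, float]]:
    """Model-predicted dose means at balanced time and mean baseline."""
    terms = list(params.index)
    base_row = np.zeros(len(terms))
    base_row[terms.index("Intercept")] = 1.0
    if spec.time_as_categorical:
        tps = [t for t in spec.timepoints if f"C(timepoint)[T.{t}]" in terms]
        for t in tps:
            base_row[terms.index(f"C(timepoint)[T.{t}]")] = 1.0 / (len(tps) + 1)
    else:
        base_row[terms.index("time_h")] = table["time_h"].mean()
    if "baseline_c" in terms:
        base_row[terms.index("baseline_c")] = table["baseline_c"].mean()
    out = {}
    for dose in DOSES:
        row = base_row.copy()
        term = f"C(dose, Treatment('{PLACEBO}'))[T.{dose}]"
        if term in terms:
            row[terms.index(term)] = 1.0
        mean = float(row @ params.to_numpy())
        var = max(float(row @ cov.to_numpy() @ row), 0.0)
        se = float(np.sqrt(var))
        out[dose] = (mean, se)
    return out


def analyze_measures(
    rows: pd.DataFrame,
    measures: list[str] | None = None,
    time_as_categorical: bool = True,
    baseline_centering: str = "within",
) -> list[DoseModelResult]:
    """Fit the dose model for every requested (or present) measure."""
    if measures is None:
        measures = sorted(rows["measure"].unique())
    results = []
    for m in measures:
        spec = DoseModelSpec(measure=m, time_as_categorical=time_as_categorical,
                             baseline_centering=baseline_centering)
        table = build_design(rows, spec)
        results.append(fit_dose_model(table, spec))
    return results


def summarize_results(
    results: list[DoseModelResult],
    alpha: float = 0.05,
    fdr_correct: bool = False,
) -> pd.DataFrame:
    """One row per measure, mirroring the trial-report layout.

    Columns: per-dose adjusted means ± SE, omnibus F and p with a
    significance flag at p < alpha, and both dose-vs-placebo contrasts with
    t, p and 95% CI.  Benjamini-Hochberg correction of the omnibus p-values
    is off by default (the per-measure tests are reported uncorrected).
    """
    if len(results) == 0:
        raise ValueError("no results to summarize")
    rows = []
    for r in results:
        row = {"measure": r.measure}
        for dose in DOSES:
            m, s = r.adjusted_means[dose]
            row[f"mean_{dose}"] = m
            row[f"se_{dose}"] = s
        row["F"] = r.F_dose
        row["p"] = r.p_dose
        for dose in ("low", "high"):
            c = r.contrasts[dose]
            row[f"{dose}_vs_placebo_t"] = c.t
            row[f"{dose}_vs_placebo_p"] = c.p
            row[f"{dose}_vs_placebo_ci_low"] = c.ci_low
            row[f"{dose}_vs_placebo_ci_high"] = c.ci_high
        rows.append(row)
    df = pd.DataFrame(rows)
    pvals = df["p"].to_numpy()
    if fdr_correct:
        df["p_adjusted"] = multipletests(pvals, method="fdr_bh")[1]
        df["significant"] = df["p_adjusted"] < alpha
    else:
        df["significant"] = pvals < alpha
    return df


def write_results(
    results: list[DoseModelResult],
    summary: pd.DataFrame,
    json_path: str | Path,
    csv_path: str | Path,
) -> None:
    """Persist full results as JSON and the summary as CSV (lossless pair)."""
    payload = {
        "df_method": results[0].df_method if results else None,
        "results": [r.to_dict() for r in results],
    }
    Path(json_path).write_text(json.dumps(payload, indent=2))
    summary.to_csv(csv_path, index=False)
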