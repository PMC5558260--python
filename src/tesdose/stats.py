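"""Mixed-effects analysis of the cohort dose table.

The measurement table holds 18 rows per subject (3 configurations x 2 sites
x 3 intensities). The response is natural-log current density; the model is
a linear mixed model with fixed factors configuration/sex/site/intensity
(reference levels ring, female, C3, 0.5 mA), optional two-way interactions,
and a random intercept per subject, fitted by REML with Wald intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

CONFIG_LEVELS = ("ring", "bi_cranial", "non_cephalic")
SEX_LEVELS = ("female", "male")
SITE_LEVELS = ("C3", "F3")
INTENSITY_LEVELS = (0.5, 1.0, 2.0)

REQUIRED_COLUMNS = ("subject_id", "sex", "configuration", "site",
                    "intensity_mA", "dose_uA_cm2")


class MeasurementTableError(ValueError):
    pass


@dataclass(frozen=True)
class AnovaResult:
    """Per-term estimates on the log scale plus variance components."""

    terms: pd.DataFrame           # coef, ci_low, ci_high, p_value, exp_coef
    subject_variance: float
    residual_variance: float
    include_interactions: bool
    n_obs: int
    n_subjects: int

    def exp_coef(self, term: str) -> float:
        return float(self.terms.loc[term, "exp_coef"])


def assemble_measurements(rows) -> pd.DataFrame:
    """Validate dose rows into the canonical long table with log_dose."""
    table = pd.DataFrame(rows) if not isinstance(rows, pd.DataFrame) \
        else rows.copy()
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise MeasurementTableError(f"missing columns: {missing_cols}")

    bad = table[table["dose_uA_cm2"] <= 0]
    if len(bad):
        rows_desc = bad[["subject_id", "configuration", "site",
                         "intensity_mA"]].to_dict("records")
        raise MeasurementTableError(f"non-positive dose in rows: {rows_desc}")

    expected = {(c, s, i) for c in CONFIG_LEVELS for s in SITE_LEVELS
                for i in INTENSITY_LEVELS}
    missing = []
    for subject, grp in table.groupby("subject_id"):
        have = {(r.configuration, r.site, float(r.intensity_mA))
                for r in grp.itertuples()}
        for cell in sorted(expected - have):
            missing.append((subject, *cell))
        if len(grp) != 18:
            missing.append((subject, f"{len(grp)} rows (expected 18)"))
    if missing:
        raise MeasurementTableError(f"incomplete condition grid: {missing}")

    table = table.copy()
    table["intensity_mA"] = table["intensity_mA"].astype(float)
    table["log_dose"] = np.log(table["dose_uA_cm2"].astype(float))
    return table.reset_index(drop=True)


def _formula(include_interactions: bool, with_sex: bool = True) -> str:
    base = "log_dose ~ C(configuration, Treatment('ring'))"
    if with_sex:
        base += " + C(sex, Treatment('female'))"
    base += (" + C(site, Treatment('C3'))"
             " + C(intensity_mA, Treatment(0.5))")
    if include_interactions:
        base += " + C(configuration, Treatment('ring')):C(site, Treatment('C3'))"
        if with_sex:
            base += (" + C(configuration, Treatment('ring'))"
                     ":C(sex, Treatment('female'))"
                     " + C(site, Treatment('C3'))"
                     ":C(sex, Treatment('female'))")
    return base


_TERM_RENAMES = {
    "C(configuration, Treatment('ring'))[T.bi_cranial]": "config[bi_cranial]",
    "C(configuration, Treatment('ring'))[T.non_cephalic]":
        "config[non_cephalic]",
    "C(sex, Treatment('female'))[T.male]": "sex[male]",
    "C(site, Treatment('C3'))[T.F3]": "site[F3]",
    "C(intensity_mA, Treatment(0.5))[T.1.0]": "intensity[1.0]",
    "C(intensity_mA, Treatment(0.5))[T.2.0]": "intensity[2.0]",
}


def _rename_term(name: str) -> str:
    if name in _TERM_RENAMES:
        return _TERM_RENAMES[name]
    parts = name.split(":")
    if len(parts) == 2:
        return ":".join(_rename_term(p) for p in parts)
    return name


def fit_mixed_model(table: pd.DataFrame,
                    include_interactions: bool = False,
                    include_sex: bool | str = "auto") -> AnovaResult:
    """REML linear mixed model of log dose with a subject random intercept.

    The sex term needs at least 2 subjects per sex; with
    ``include_sex="auto"`` it is dropped (with its interactions) on smaller
    cohorts instead of failing.
    """
    subjects = table["subject_id"].unique()
    sex_ok = all(table.loc[table["sex"] == s, "subject_id"].nunique() >= 2
                 for s in SEX_LEVELS)
    if include_sex == "auto":
        with_sex = sex_ok
    else:
        with_sex = bool(include_sex)
    if with_sex and not sex_ok:
        raise MeasurementTableError(
            "need at least 2 subjects per sex for the sex term")

    model = smf.mixedlm(_formula(include_interactions, with_sex=with_sex),
                        data=table, groups=table["subject_id"])
    fit = None
    last_err: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            fit = model.fit(reml=True, method=method, maxiter=500)
            break
        except np.linalg.LinAlgError as err:
            last_err = err
    if fit is None:
        raise MeasurementTableError(
            "singular mixed-model fit; try the main-effects-only model"
        ) from last_err

    fe = fit.fe_params
    ci = fit.conf_int().loc[fe.index]
    terms = pd.DataFrame({
        "coef": fe.values,
        "ci_low": ci[0].values,
        "ci_high": ci[1].values,
        "p_value": fit.pvalues.loc[fe.index].values,
        "exp_coef": np.exp(fe.values),
    }, index=[_rename_term(t) for t in fe.index])

    return AnovaResult(terms=terms,
                       subject_variance=float(fit.cov_re.iloc[0, 0]),
                       residual_variance=float(fit.scale),
                       include_interactions=include_interactions,
                       n_obs=len(table), n_subjects=len(subjects))


def cell_mean_contrasts(table: pd.DataFrame) -> dict[str, float]:
    """Main-effect contrasts computed directly from marginal means of
    log dose — the balanced-design oracle for the mixed model."""
    m = table.groupby("configuration")["log_dose"].mean()
    s = table.groupby("sex")["log_dose"].mean()
    loc = table.groupby("site")["log_dose"].mean()
    i = table.groupby("intensity_mA")["log_dose"].mean()
    return {
        "config[bi_cranial]": float(m["bi_cranial"] - m["ring"]),
        "config[non_cephalic]": float(m["non_cephalic"] - m["ring"]),
        "sex[male]": float(s["male"] - s["female"]),
        "site[F3]": float(loc["F3"] - loc["C3"]),
        "intensity[1.0]": float(i[1.0] - i[0.5]),
        "intensity[2.0]": float(i[2.0] - i[0.5]),
    }


def cross_site_correlation(table: pd.DataFrame,
                           intensity_mA: float = 2.0) -> pd.DataFrame:
    """Pearson correlation of C3 vs F3 dose across subjects, per
    configuration, at one intensity (scatter coordinates included)."""
    sub = table[np.isclose(table["intensity_mA"].astype(float), intensity_mA)]
    if sub["subject_id"].nunique() < 3:
        raise MeasurementTableError(
            "need at least 3 subjects for cross-site correlation")
    out = []
    for config, grp in sub.groupby("configuration"):
        wide = grp.pivot(index="subject_id", columns="site",
                         values="dose_uA_cm2")
        if wide[["C3", "F3"]].isna().any().any():
            raise MeasurementTableError(
                f"both sites required for every subject ({config})")
        r = float(np.corrcoef(wide["C3"], wide["F3"])[0, 1])
        out.append({"configuration": config, "intensity_mA": intensity_mA,
                    "r": r, "n_subjects": len(wide),
                    "c3_doses": wide["C3"].tolist(),
                    "f3_doses": wide["F3"].tolist()})
    return pd.DataFrame(out).set_index("configuration")


def summarize_cells(table: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) of untransformed dose per sex x configuration x site x
    intensity, plus overall (sex = 'all') rows."""
    def agg(grp_cols):
        g = table.groupby(grp_cols, as_index=False)["dose_uA_cm2"] \
            .agg(mean_dose="mean", sd_dose=lambda x: x.std(ddof=1)
                 if len(x) > 1 else 0.0, n="count")
        return g

    by_sex = agg(["sex", "configuration", "site", "intensity_mA"])
    overall = agg(["configuration", "site", "intensity_mA"])
    overall.insert(0, "sex", "all")
    return pd.concat([by_sex, overall], ignore_index=True)


def qq_diagnostics(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Normal QQ pairs of condition-cell residuals for raw, log and
    square-root transforms of dose."""
    from scipy import stats as sps

    transforms = {"raw": lambda d: d, "log": np.log, "sqrt": np.sqrt}
    cells = ["configuration", "site", "intensity_mA"]
    out = {}
    for name, f in transforms.items():
        y = f(table["dose_uA_cm2"].astype(float))
        resid = y - y.groupby([table[c] for c in cells]).transform("mean")
        resid = np.sort(resid.values)
        sd = resid.std(ddof=1)
        if sd > 0:
            resid = resid / sd
        n = len(resid)
        theo = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        out[name] = pd.DataFrame({"theoretical": theo, "observed": resid})
    return out
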