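"""Univariate and covariate analyses of per-patient average nuclear D.

Implements the cohort-level statistics around the D biomarker: control
normalization of patient mean nuclear D, ANCOVA of normalized D on group and
demographic covariates (type-II F tests), within-group subgroup regressions,
age adjustment by the control-group slope, the average-D ROC, and rank-sum
comparisons within pack-year smoking strata (< 20 vs >= 20, the LDCT
eligibility cut).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import mannwhitneyu

from .classify import roc_auc

__all__ = [
    "PatientD",
    "AncovaReport",
    "patient_mean_d",
    "ancova_d",
    "subgroup_regression",
    "age_adjust",
    "average_d_auc",
    "packyear_subgroup_test",
]


@dataclass
class PatientD:
    patient_id: str
    group: str
    mean_nuclear_d: float
    normalized_d: float
    n_cells: int
    age: float = np.nan
    pack_years: float = np.nan
    gender: str = ""
    race: str = ""


def patient_mean_d(cell_table: pd.DataFrame) -> list[PatientD]:
    """Per-patient average nuclear D, normalized by the control-group mean.

    ``cell_table`` has one row per cell with columns ``patient_id``,
    ``group``, ``cell_mean_d`` and optionally ``keep`` (QC verdict) plus
    demographic columns.  The patient statistic is the unweighted mean of
    per-cell in-mask mean D over kept cells; normalization divides by the
    mean over control patients, per site when a ``site`` column is present.
    Patients with zero kept cells are excluded with a warning.
    """
    df = cell_table.copy()
    if "keep" in df.columns:
        dropped = df.loc[~df["keep"], "patient_id"].unique()
        df = df[df["keep"]]
    patients: list[PatientD] = []
    demo_cols = [c for c in ("age", "pack_years", "gender", "race", "site")
                 if c in df.columns]
    grouped = df.groupby("patient_id", sort=True)
    all_ids = cell_table["patient_id"].unique()
    for pid in all_ids:
        if pid not in grouped.groups:
            warnings.warn(f"patient {pid} has no kept cells; excluded")
            continue
        sub = grouped.get_group(pid)
        rec = PatientD(
            patient_id=str(pid),
            group=str(sub["group"].iloc[0]),
            mean_nuclear_d=float(sub["cell_mean_d"].mean()),
            normalized_d=np.nan,
            n_cells=int(len(sub)),
        )
        for c in demo_cols:
            if c != "site":
                setattr(rec, c, sub[c].iloc[0])
        patients.append(rec)
    # control normalization (per site if available)
    frame = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "group": [p.group for p in patients],
            "mean": [p.mean_nuclear_d for p in patients],
            "site": [
                df[df["patient_id"] == p.patient_id]["site"].iloc[0]
                if "site" in df.columns else "all"
                for p in patients
            ],
        }
    )
    for site, sub in frame.groupby("site"):
        ctrl = sub.loc[sub["group"] == "control", "mean"]
        if ctrl.empty:
            raise ValueError(f"no control patients in site {site!r} to normalize by")
        denom = float(ctrl.mean())
        for p in patients:
            row = frame[frame["patient_id"] == p.patient_id]
            if row["site"].iloc[0] == site:
                p.normalized_d = p.mean_nuclear_d / denom
    return patients


def _patients_frame(patients) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "group": [p.group for p in patients],
            "normalized_d": [p.normalized_d for p in patients],
            "age": [p.age for p in patients],
            "pack_years": [p.pack_years for p in patients],
            "gender": [p.gender for p in patients],
            "race": [p.race for p in patients],
        }
    )


@dataclass
class AncovaReport:
    formula: str
    terms: dict  # term -> {slope, F, p}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.terms).T


def ancova_d(
    patients,
    covariates=("group", "age", "pack_years", "gender", "race"),
) -> AncovaReport:
    """ANCOVA: linear model of normalized D with type-II F tests per term.

    Categorical covariates are coded with treatment contrasts; the reported
    slope for a categorical term is the coefficient of its non-reference
    level.  Rank deficiency raises an error naming the collinear columns.
    """
    df = _patients_frame(patients) if not isinstance(patients, pd.DataFrame) else patients.copy()
    if len(df) < 10:
        raise ValueError("need at least 10 patients for ANCOVA")
    categorical = {"group", "gender", "race"}
    parts = []
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
        parts.append(f"C({c})" if c in categorical else c)
    formula = "normalized_d ~ " + " + ".join(parts)
    model = smf.ols(formula, data=df)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        # identify collinear columns by incremental rank growth
        names, bad = model.exog_names, []
        for j in range(1, model.exog.shape[1]):
            if np.linalg.matrix_rank(model.exog[:, : j + 1]) == np.linalg.matrix_rank(
                model.exog[:, :j]
            ):
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    fit = model.fit()
    table = sm.stats.anova_lm(fit, typ=2)
    terms: dict[str, dict] = {}
    for c, part in zip(covariates, parts):
        coef = next(
            (fit.params[n] for n in fit.params.index if n.startswith(part)), np.nan
        )
        terms[c] = {
            "slope": float(coef),
            "F": float(table.loc[part, "F"]),
            "p": float(table.loc[part, "PR(>F)"]),
        }
    return AncovaReport(formula=formula, terms=terms)


def subgroup_regression(patients, covariate: str, subgroup_filter=None):
    """OLS slope (and 95% CI) of normalized D on a covariate within a subgroup.

    ``subgroup_filter`` is a predicate over PatientD (or a boolean mask for
    DataFrame input); e.g. controls only.
    """
    if isinstance(patients, pd.DataFrame):
        df = patients if subgroup_filter is None else patients[subgroup_filter]
    else:
        sel = patients if subgroup_filter is None else [
            p for p in patients if subgroup_filter(p)
        ]
        df = _patients_frame(sel)
    if len(df) < 3:
        raise ValueError("subgroup too small for regression (need >= 3 patients)")
    x = sm.add_constant(np.asarray(df[covariate], dtype=float))
    fit = sm.OLS(np.asarray(df["normalized_d"], dtype=float), x).fit()
    ci = fit.conf_int()[1]
    return float(fit.params[1]), (float(ci[0]), float(ci[1]))


def age_adjust(patients, control_slope: float, control_mean_age: float | None = None):
    """Remove the control-group age trend from normalized D.

    adjusted = normalized_d - slope * (age - control mean age).  Patients
    with missing age are flagged (returned unadjusted, ``age_adjusted`` =
    False in the second return value).
    """
    ctrl_ages = [p.age for p in patients if p.group == "control" and np.isfinite(p.age)]
    if control_mean_age is None:
        control_mean_age = float(np.mean(ctrl_ages))
    adjusted, flags = [], []
    for p in patients:
        if np.isfinite(p.age):
            adjusted.append(
                p.normalized_d - control_slope * (p.age - control_mean_age)
            )
            flags.append(True)
        else:
            adjusted.append(p.normalized_d)
            flags.append(False)
    return np.asarray(adjusted), np.asarray(flags)


def average_d_auc(patients, values=None) -> float:
    """Rank AUC of (normalized or adjusted) average D as a 1-D classifier."""
    labels = np.array([1 if p.group == "case" else 0 for p in patients])
    scores = (
        np.asarray(values, dtype=float)
        if values is not None
        else np.array([p.normalized_d for p in patients])
    )
    return roc_auc(scores, labels)


def packyear_subgroup_test(patients, cut: float = 20.0) -> dict:
    """Case-vs-control rank-sum within pack-year strata (< cut, >= cut).

    Uses the exact rank-sum null when min(n1, n0) <= 10 and there are no
    ties; an empty stratum is reported as not computable, never fatal.
    """
    out = {}
    for name, pred in (
        (f"pky_lt_{cut:g}", lambda p: p.pack_years < cut),
        (f"pky_ge_{cut:g}", lambda p: p.pack_years >= cut),
    ):
        case = [p.normalized_d for p in patients if p.group == "case" and pred(p)]
        ctrl = [p.normalized_d for p in patients if p.group == "control" and pred(p)]
        entry = {
            "n_case": len(case),
            "n_control": len(ctrl),
            "median_case": float(np.median(case)) if case else np.nan,
            "median_control": float(np.median(ctrl)) if ctrl else np.nan,
        }
        if not case or not ctrl:
            entry["p"] = None
            entry["note"] = "empty stratum; not computable"
        else:
            method = "exact" if min(len(case), len(ctrl)) <= 10 else "auto"
            try:
                res = mannwhitneyu(case, ctrl, alternative="two-sided", method=method)
            except ValueError:  # ties prevent the exact null
                res = mannwhitneyu(case, ctrl, alternative="two-sided", method="auto")
            entry["p"] = float(res.pvalue)
        out[name] = entry
    return out
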