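"""Overall-survival analysis stratified by repetitive-element methylation.

The marker is dichotomized at the ROC-derived cutoff (the threshold closest
to the upper-left corner of the ROC curve for vital status at end of
follow-up), Kaplan-Meier curves and log-rank tests compare the groups, and
Cox proportional-hazards models (optionally stratified, e.g. by treatment
center) give unadjusted and adjusted hazard ratios.  Efron tie handling is
the default; Breslow is selectable for compatibility with software whose
default differs.

The published LINE-1 cutoff from the original 74-patient myeloma cohort
(36.0% methylation) is shipped as ``PUBLISHED_LINE1_CUTOFF`` for
reproduction runs, since it cannot be re-derived without patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "PUBLISHED_LINE1_CUTOFF",
    "SurvivalFit",
    "roc_cutoff",
    "km_estimate",
    "logrank",
    "cox_fit",
    "survival_report",
    "read_clinical",
]

PUBLISHED_LINE1_CUTOFF = 36.0

CLINICAL_COLS = ["sample", "os_days", "event"]


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns {missing}")
    if (df["os_days"] < 0).any():
        raise ValueError("negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event flag must be 0/1")
    if "iss_stage" in df.columns and not df["iss_stage"].dropna().isin([1, 2, 3]).all():
        raise ValueError("ISS stage must be 1, 2 or 3")
    return df.set_index("sample")


def roc_cutoff(marker, outcome, direction: str = "lower") -> float:
    """Marker threshold closest to the ROC upper-left corner.

    ``direction="lower"`` treats low marker values as predicting the event
    (hypomethylation -> death).  Candidate thresholds are midpoints between
    sorted distinct marker values; the threshold minimizing
    (1 - sensitivity)^2 + (1 - specificity)^2 is returned, ties broken
    toward the lower threshold.
    """
    marker = np.asarray(marker, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if outcome.min() == outcome.max():
        raise ValueError("both outcome classes must be present")
    distinct = np.unique(marker)
    if len(distinct) < 2:
        raise ValueError("marker is constant")
    thresholds = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos = int(outcome.sum())
    n_neg = len(outcome) - n_pos
    best_thr, best_d2 = None, np.inf
    for thr in thresholds:
        pred = marker < thr if direction == "lower" else marker > thr
        sens = (pred & (outcome == 1)).sum() / n_pos
        spec = (~pred & (outcome == 0)).sum() / n_neg
        d2 = (1 - sens) ** 2 + (1 - spec) ** 2
        if d2 < best_d2:  # strict: ties keep the earlier (lower) threshold
            best_thr, best_d2 = float(thr), float(d2)
    return best_thr


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate with Greenwood variance.

    Returns one row per distinct event/censoring time with the at-risk and
    observed counts, the survival estimate and its Greenwood variance.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("no observations")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), 0.0)
    greenwood = surv.to_numpy() ** 2 * np.cumsum(terms)
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": n.astype(int),
            "observed": d.astype(int),
            "survival": surv.to_numpy(),
            "greenwood_var": greenwood,
        }
    )


def logrank(groups: list[tuple]) -> tuple[float, float]:
    """Log-rank chi-square across >= 2 groups of (times, events)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    times = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    events = np.concatenate([np.asarray(e, dtype=int) for _, e in groups])
    labels = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(groups)])
    if events.sum() == 0:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalFit:
    """Cox model results: hazard ratios with 95% CIs and Wald P per covariate."""

    summary: pd.DataFrame  # index: covariate; columns hr, ci_low, ci_high, p, coef, se
    n: int
    events: int
    strata: str | None = None
    ties: str = "efron"
    warnings: list[str] = field(default_factory=list)

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def cox_fit(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "os_days",
    event_col: str = "event",
    strata: str | None = None,
    ties: str = "efron",
) -> SurvivalFit:
    """Stratified Cox proportional-hazards fit (partial likelihood).

    Raises on constant covariates (no information) and surfaces complete
    separation / non-convergence as warnings on the fit.
    """
    data = df.dropna(subset=[duration_col, event_col] + covariates + ([strata] if strata else []))
    n, n_events = len(data), int(data[event_col].sum())
    if n_events < len(covariates):
        raise ValueError(f"{n_events} events cannot support {len(covariates)} covariates")
    exog = data[covariates].astype(float)
    for c in covariates:
        if exog[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant: no information")
    model = PHReg(
        data[duration_col].to_numpy(dtype=float),
        exog.to_numpy(),
        status=data[event_col].to_numpy(dtype=int),
        strata=data[strata].to_numpy() if strata else None,
        ties=ties,
    )
    warnings: list[str] = []
    try:
        res = model.fit(disp=False)
    except Exception as exc:  # non-convergence surfaces with context
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if np.any(np.abs(coef) > 15):
        warnings.append("extreme coefficient: possible complete separation")
    z = 1.959963984540054
    summary = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "hr": np.exp(coef),
            "ci_low": np.exp(coef - z * se),
            "ci_high": np.exp(coef + z * se),
            "p": np.asarray(res.pvalues, dtype=float),
        },
        index=pd.Index(covariates, name="covariate"),
    )
    return SurvivalFit(summary, n, n_events, strata=strata, ties=ties, warnings=warnings)


def survival_report(
    clinical: pd.DataFrame,
    profiles: pd.DataFrame,
    element: str = "line1",
    cutoff: str | float = "auto",
    strata: str | None = "center",
    adjust_covariates: tuple[str, ...] = ("age", "sex_male", "iss_stage", "chr13_loss"),
) -> dict:
    """Full survival stratification report for one methylation element.

    Dichotomizes at the ROC cutoff (or a given value), and emits KM tables
    for each available time origin, the log-rank P, unadjusted and adjusted
    hazard ratios for the hypomethylated group, and the ISS-stage trend of
    methylation.  Samples missing from either table are reported, not fatal.
    """
    common = clinical.index.intersection(profiles.index)
    unmatched = sorted(set(clinical.index).symmetric_difference(profiles.index))
    data = clinical.loc[common].copy()
    data[element] = profiles.loc[common, element]
    data = data.dropna(subset=[element, "os_days", "event"])
    if cutoff == "auto":
        cutoff_value = roc_cutoff(data[element], data["event"])
    else:
        cutoff_value = float(cutoff)
    data["hypomethylated"] = (data[element] < cutoff_value).astype(int)
    report: dict = {
        "element": element,
        "cutoff": float(cutoff_value),
        "n": int(len(data)),
        "events": int(data["event"].sum()),
        "n_hypomethylated": int(data["hypomethylated"].sum()),
        "unmatched_samples": unmatched,
    }
    origins = [("os_days", "collection")]
    if "os_diagnosis_days" in data.columns and data["os_diagnosis_days"].notna().any():
        origins.append(("os_diagnosis_days", "diagnosis"))
    if data["hypomethylated"].nunique() < 2:
        report["untestable"] = "cutoff does not split the cohort into two groups"
        return report
    km: dict = {}
    for col, label in origins:
        sub = data.dropna(subset=[col])
        grp = [
            (sub.loc[sub["hypomethylated"] == g, col], sub.loc[sub["hypomethylated"] == g, "event"])
            for g in (0, 1)
        ]
        chi2, p = logrank(grp)
        km[label] = {
            "logrank_chi2": chi2,
            "logrank_p": p,
            "km_high": km_estimate(*grp[0]),
            "km_low": km_estimate(*grp[1]),
        }
    report["survival"] = km
    report["unadjusted"] = cox_fit(data, ["hypomethylated"], strata=None)
    adj = [c for c in adjust_covariates if c in data.columns and data[c].notna().all()]
    strata_col = strata if strata and strata in data.columns else None
    if adj and data["event"].sum() > len(adj) + 1:
        report["adjusted"] = cox_fit(data, ["hypomethylated"] + adj, strata=strata_col)
    if "iss_stage" in data.columns and data["iss_stage"].nunique() > 1:
        t, p = _iss_trend(data, element)
        report["iss_trend"] = {"t": t, "p": p,
                              "stage_means": data.groupby("iss_stage")[element].mean().to_dict()}
    return report


def _iss_trend(data: pd.DataFrame, element: str) -> tuple[float, float]:
    from .stats import linear_trend

    sub = data.dropna(subset=["iss_stage", element])
    return linear_trend(sub[element].to_numpy(), sub["iss_stage"].to_numpy(dtype=int))
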