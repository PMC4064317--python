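"""Association statistics linking repetitive-element methylation to
chromosomal aberrations.

Methylation profiles are a DataFrame indexed by sample id with one column
per element (percent methylation, 0-100).  Group comparisons use Welch's
unequal-variance t-test (Games-Howell pairwise comparisons for three or
more groups); burden correlations are Pearson on log10(count + 1); ordered
group means are tested with the linear polynomial contrast in a one-way
model.  No multiple-testing adjustment is applied by default, matching the
single-cohort exploratory design; Benjamini-Hochberg is available.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "welch_t",
    "games_howell",
    "volcano",
    "corr_burden",
    "linear_trend",
    "element_correlations",
]

ELEMENTS = ["line1", "alu_ya5", "alu_yb8", "sat_alpha"]


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch two-sample t-test; returns (mean(a) - mean(b), t, two-sided P)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean() - b.mean()), float(t), float(p)


def games_howell(groups: dict | list) -> pd.DataFrame:
    """Games-Howell pairwise comparisons for >= 3 groups.

    Uses the studentized-range distribution with Welch-Satterthwaite degrees
    of freedom per pair.  Returns one row per pair with the mean difference
    and the adjusted P value.
    """
    if not isinstance(groups, dict):
        groups = {str(i): g for i, g in enumerate(groups)}
    if len(groups) < 3:
        raise ValueError("games_howell needs >= 3 groups; use welch_t for two")
    stats_by_group = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
        stats_by_group[name] = (v.mean(), v.var(ddof=1), len(v))
    k = len(groups)
    rows = []
    for ga, gb in combinations(stats_by_group, 2):
        ma, va, na = stats_by_group[ga]
        mb, vb, nb = stats_by_group[gb]
        se2 = va / na + vb / nb
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        q = abs(ma - mb) / np.sqrt(se2 / 2.0)
        p = float(stats.studentized_range.sf(q, k, df))
        rows.append({"group_a": ga, "group_b": gb, "delta": ma - mb, "q": q, "df": df, "p": p})
    return pd.DataFrame(rows)


def volcano(
    profiles: pd.DataFrame,
    arm_aberrations,
    element: str = "line1",
    state: str = "loss",
    alpha: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-arm methylation difference between samples with and without an
    aberration of ``state`` on that arm.

    delta is mean(with aberration) - mean(without); rows where either group
    has fewer than two samples with data are marked untestable.  For losses a
    row is flagged when P < alpha with delta < 0 (hypomethylation with loss);
    for gains, when P < alpha.
    """
    meth = profiles[element].dropna()
    arm_samples: dict[str, set] = {}
    for ab in arm_aberrations:
        if ab.state == state:
            arm_samples.setdefault(ab.arm_label, set()).add(ab.sample)
    rows = []
    for arm in sorted(arm_samples):
        with_ab = meth[meth.index.isin(arm_samples[arm])]
        without = meth[~meth.index.isin(arm_samples[arm])]
        if len(with_ab) < 2 or len(without) < 2:
            rows.append(
                {"arm": arm, "state": state, "delta": np.nan, "p": np.nan,
                 "n_with": len(with_ab), "n_without": len(without),
                 "testable": False, "flagged": False}
            )
            continue
        delta, _, p = welch_t(with_ab, without)
        rows.append(
            {"arm": arm, "state": state, "delta": delta, "p": p,
             "n_with": len(with_ab), "n_without": len(without),
             "testable": True, "flagged": False}
        )
    out = pd.DataFrame(
        rows,
        columns=["arm", "state", "delta", "p", "n_with", "n_without", "testable", "flagged"],
    )
    if adjust == "bh" and out["testable"].any():
        from statsmodels.stats.multitest import multipletests

        testable = out["testable"]
        out.loc[testable, "p_adj"] = multipletests(out.loc[testable, "p"], method="fdr_bh")[1]
        pcol = "p_adj"
    else:
        pcol = "p"
    sig = out["testable"] & (out[pcol] < alpha)
    if state == "loss":
        sig &= out["delta"] < 0
    out["flagged"] = sig
    return out


def corr_burden(
    profiles: pd.DataFrame,
    burden: pd.Series,
    element: str = "line1",
) -> tuple[float, tuple[float, float], float]:
    """Pearson correlation between percent methylation and log10(count + 1)
    of an aberration burden, with a Fisher-z 95% CI."""
    joined = pd.concat([profiles[element], burden], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 paired observations")
    y = joined.iloc[:, 0].to_numpy(dtype=float)
    x = np.log10(joined.iloc[:, 1].to_numpy(dtype=float) + 1.0)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in methylation or burden")
    r, p = stats.pearsonr(y, x)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(len(joined) - 3)
    ci = (float(np.tanh(z - 1.959963984540054 * se)), float(np.tanh(z + 1.959963984540054 * se)))
    return float(r), ci, float(p)


def linear_trend(values, groups) -> tuple[float, float]:
    """Linear polynomial contrast across ordered groups in a one-way model.

    Group scores are the ranks 1..K of the ordered levels; the contrast is
    tested with the pooled within-group mean square on N - K df.  With two
    groups this reduces to the pooled two-sample t-test.  Returns (t, P).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [g for g in pd.unique(groups)]
    levels.sort()
    k = len(levels)
    if k < 2:
        raise ValueError("need >= 2 non-empty ordered groups")
    means, ns, sse = [], [], 0.0
    for lev in levels:
        v = values[groups == lev]
        means.append(v.mean())
        ns.append(len(v))
        sse += ((v - v.mean()) ** 2).sum()
    n_total = int(sum(ns))
    df = n_total - k
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    scores = np.arange(1, k + 1, dtype=float)
    c = scores - scores.mean()
    mse = sse / df
    contrast = float(np.dot(c, means))
    se = np.sqrt(mse * float(np.sum(c**2 / np.asarray(ns))))
    t = contrast / se
    return float(t), float(2 * stats.t.sf(abs(t), df))


def element_correlations(profiles: pd.DataFrame, elements=None) -> pd.DataFrame:
    """Pairwise Pearson correlations (with P) between element methylation levels."""
    elements = [e for e in (elements or ELEMENTS) if e in profiles.columns]
    complete = profiles[elements].dropna()
    if len(complete) < 3:
        raise ValueError("need >= 3 complete profiles")
    rows = []
    for a, b in combinations(elements, 2):
        r, p = stats.pearsonr(complete[a], complete[b])
        rows.append({"element_a": a, "element_b": b, "r": float(r), "p": float(p), "n": len(complete)})
    return pd.DataFrame(rows)
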