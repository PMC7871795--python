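"""Group statistics on pit counts, per-cluster pit depth, and asymmetry.

Between-group effects are estimated by ordinary least squares with a group
dummy and age as covariate; age effects by simple regression.  Cluster-wise
families are corrected with Benjamini-Hochberg FDR, with the family size
fixed at the full parcellation (skipped clusters still count).  Hemispheric
asymmetry uses AI = (L - R)/(L + R) on deepest-pit depth per symmetric
cluster, and within-group left/right differences use a one-within-factor
repeated-measures ANOVA (numerically the squared paired t)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "group_age_regression",
    "age_regression",
    "bh_fdr",
    "per_cluster_tests",
    "asymmetry_index",
    "asymmetry_table",
    "ai_group_tests",
    "within_group_hemisphere_test",
    "subtype_comparison",
    "ALPHA_LEVEL",
]

ALPHA_LEVEL = 0.05


@dataclass
class StatResult:
    """One test's outcome: effect estimate, t (or F), two-tailed p, BH q."""

    effect: float
    statistic: float
    p_value: float
    n_used: int
    q_value: float = np.nan
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        q = self.q_value if np.isfinite(self.q_value) else self.p_value
        return bool(q < ALPHA_LEVEL)


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    records = pd.DataFrame(records)
    for col in ("group", "age"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    bad = set(records["group"].unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group labels {bad}")
    if (records["age"] <= 0).any():
        raise ValueError("ages must be positive")
    return records


def _ols_dummy(y: np.ndarray, dummy: np.ndarray, age: np.ndarray) -> StatResult:
    """OLS y ~ 1 + dummy + age; returns the dummy coefficient's test."""
    y = np.asarray(y, dtype=np.float64)
    if np.ptp(y) == 0:
        # constant outcome: zero effect by construction, nothing to test
        return StatResult(0.0, 0.0, 1.0, len(y), degenerate=True)
    X = sm.add_constant(np.column_stack([dummy, age]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (one group only, or collinear)")
    fit = sm.OLS(y, X).fit()
    return _coef_result(fit, y)


def _coef_result(fit, y, idx: int = 1) -> StatResult:
    """Test of one OLS coefficient, guarding the zero-residual limit."""
    effect = float(fit.params[idx])
    t = float(fit.tvalues[idx])
    p = float(fit.pvalues[idx])
    if not np.isfinite(p):
        # perfect fit: no residual variance left to test against
        if abs(effect) <= 1e-8 * max(1.0, float(np.ptp(y))):
            return StatResult(effect, 0.0, 1.0, int(fit.nobs), degenerate=True)
        return StatResult(effect, np.inf, 0.0, int(fit.nobs), degenerate=True)
    return StatResult(effect, t, p, int(fit.nobs))


def group_age_regression(y, records: pd.DataFrame) -> StatResult:
    """Between-group effect on y, adjusting for age.

    OLS y ~ intercept + group(case=1) + age; two-tailed t test on the group
    coefficient.  Requires at least 3 subjects per group.
    """
    records = _check_records(records)
    y = np.asarray(y, dtype=np.float64)
    if y.shape[0] != len(records):
        raise ValueError("y length does not match records")
    counts = records["group"].value_counts()
    if counts.get("case", 0) < 3 or counts.get("control", 0) < 3:
        raise ValueError("need >= 3 subjects per group")
    dummy = (records["group"] == "case").to_numpy(dtype=float)
    return _ols_dummy(y, dummy, records["age"].to_numpy(dtype=float))


def age_regression(y, records: pd.DataFrame) -> StatResult:
    """Simple linear regression of y on age; two-tailed t on the slope."""
    records = _check_records(records)
    y = np.asarray(y, dtype=np.float64)
    if np.ptp(y) == 0:
        return StatResult(0.0, 0.0, 1.0, len(y), degenerate=True)
    X = sm.add_constant(records["age"].to_numpy(dtype=float))
    fit = sm.OLS(y, X).fit()
    return _coef_result(fit, y)


def bh_fdr(p_values: np.ndarray, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg q-values, NaN-aware, with an explicit family size.

    family_size defaults to the number of finite p-values; a larger value
    pads the family with never-rejected tests (clusters skipped for data
    reasons still count toward the correction).
    """
    p = np.asarray(p_values, dtype=np.float64)
    finite = np.isfinite(p)
    m_obs = int(finite.sum())
    if family_size is None:
        family_size = m_obs
    if family_size < m_obs:
        raise ValueError("family_size smaller than number of observed p-values")
    q = np.full_like(p, np.nan)
    if m_obs == 0:
        return q
    padded = np.concatenate([p[finite], np.ones(family_size - m_obs)])
    _, q_padded, _, _ = multipletests(padded, alpha=ALPHA_LEVEL, method="fdr_bh")
    q[finite] = q_padded[:m_obs]
    return q


def per_cluster_tests(
    table: pd.DataFrame,
    records: pd.DataFrame,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Group difference in deepest-pit depth for every cluster, FDR-corrected.

    table: subjects x clusters with NaN where the subject has no pit.
    Subjects missing a cluster are dropped from that cluster's regression;
    clusters with fewer than 3 subjects in either group are skipped (NaN
    row) but still count in the BH family.
    """
    records = _check_records(records)
    if len(table) != len(records):
        raise ValueError("depth table and records have different subject counts")
    if family_size is None:
        family_size = table.shape[1]
    rows = []
    for cid in table.columns:
        col = table[cid]
        mask = col.notna().to_numpy()
        sub = records.loc[mask]
        n_case = int((sub["group"] == "case").sum())
        n_ctrl = int((sub["group"] == "control").sum())
        if n_case < 3 or n_ctrl < 3:
            warnings.warn(f"cluster {cid}: <3 subjects per group, skipped")
            rows.append((cid, np.nan, np.nan, np.nan, mask.sum(), True))
            continue
        res = group_age_regression(col[mask].to_numpy(), sub)
        rows.append((cid, res.effect, res.statistic, res.p_value, res.n_used,
                     res.degenerate))
    out = pd.DataFrame(
        rows, columns=["cluster", "effect", "t", "p", "n", "degenerate"]
    ).set_index("cluster")
    out["q"] = bh_fdr(out["p"].to_numpy(), family_size)
    out["significant"] = out["q"] < ALPHA_LEVEL
    return out


def asymmetry_index(left: float, right: float) -> float:
    """AI = (L - R)/(L + R) on nonnegative depths.

    +1 is completely left-lateralized, -1 completely right-lateralized.
    Undefined (NaN) when L + R <= 0.
    """
    if left + right <= 0:
        return np.nan
    return (left - right) / (left + right)


def asymmetry_table(left_table: pd.DataFrame, right_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-symmetric-cluster AI from paired L/R depth tables.

    Cells where either hemisphere is missing, or where L + R <= 0, are NaN.
    """
    if not left_table.columns.equals(right_table.columns) or not left_table.index.equals(
        right_table.index
    ):
        raise ValueError("left/right tables must share subjects and clusters")
    L = left_table.to_numpy(dtype=np.float64)
    R = right_table.to_numpy(dtype=np.float64)
    total = L + R
    with np.errstate(invalid="ignore", divide="ignore"):
        ai = np.where(total > 0, (L - R) / total, np.nan)
    return pd.DataFrame(ai, index=left_table.index, columns=left_table.columns)


def ai_group_tests(
    left_table: pd.DataFrame,
    right_table: pd.DataFrame,
    records: pd.DataFrame,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Group differences in depth asymmetry per symmetric cluster."""
    ai = asymmetry_table(left_table, right_table)
    return per_cluster_tests(ai, records, family_size)


def within_group_hemisphere_test(
    left_table: pd.DataFrame,
    right_table: pd.DataFrame,
    records: pd.DataFrame,
    group: str,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Left/right depth difference per symmetric cluster within one group.

    One-within-factor (hemisphere) repeated-measures ANOVA on subjects with
    both hemispheres observed; F equals the squared paired t.  Clusters
    with fewer than 3 complete pairs are skipped; BH-FDR across clusters
    within the group.
    """
    records = _check_records(records)
    keep = (records["group"] == group).to_numpy()
    if keep.sum() == 0:
        raise ValueError(f"no subjects in group {group!r}")
    L_all = left_table.loc[keep]
    R_all = right_table.loc[keep]
    if family_size is None:
        family_size = left_table.shape[1]
    rows = []
    for cid in left_table.columns:
        pair_mask = L_all[cid].notna() & R_all[cid].notna()
        n = int(pair_mask.sum())
        if n < 3:
            rows.append((cid, np.nan, np.nan, np.nan, n, True))
            continue
        lvals = L_all.loc[pair_mask, cid].to_numpy(dtype=np.float64)
        rvals = R_all.loc[pair_mask, cid].to_numpy(dtype=np.float64)
        diff = lvals - rvals
        mean_diff = float(diff.mean())
        if np.ptp(diff) == 0:
            # zero within-subject variance: F undefined; report the
            # degenerate limit (p=1 for no shift, p=0 for a constant shift)
            rows.append(
                (cid, mean_diff, 0.0 if mean_diff == 0 else np.inf,
                 1.0 if mean_diff == 0 else 0.0, n, True)
            )
            continue
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "hemisphere": np.tile(["left", "right"], n),
                "depth": np.column_stack([lvals, rvals]).ravel(),
            }
        )
        fit = AnovaRM(long, depvar="depth", subject="subject",
                      within=["hemisphere"]).fit()
        F = float(fit.anova_table["F Value"].iloc[0])
        p = float(fit.anova_table["Pr > F"].iloc[0])
        rows.append((cid, mean_diff, F, p, n, False))
    out = pd.DataFrame(
        rows, columns=["cluster", "mean_diff", "F", "p", "n", "degenerate"]
    ).set_index("cluster")
    out["q"] = bh_fdr(out["p"].to_numpy(), family_size)
    out["significant"] = out["q"] < ALPHA_LEVEL
    return out


def subtype_comparison(y, records: pd.DataFrame) -> StatResult:
    """Combined vs inattentive subtype difference among cases, age-adjusted.

    OLS y ~ intercept + subtype(combined=1) + age on case subjects only.
    """
    records = _check_records(records)
    if "subtype" not in records.columns:
        raise ValueError("records missing 'subtype' column")
    y = np.asarray(y, dtype=np.float64)
    keep = (records["group"] == "case").to_numpy()
    sub = records.loc[keep]
    y = y[keep]
    present = set(sub["subtype"].unique()) - {"none"}
    if len(present) < 2:
        raise ValueError(f"need both subtypes among cases, found {present}")
    dummy = (sub["subtype"] == "combined").to_numpy(dtype=float)
    return _ols_dummy(y, dummy, sub["age"].to_numpy(dtype=float))
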