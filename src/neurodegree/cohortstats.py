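"""Group-level statistics for the two-group degree-distribution analysis.

Covers the demographic contrasts (two-tailed Pearson chi-square with Yates
correction for the gender table, pooled two-sample t-tests for the
continuous variables), the two covariate-adjusted GLMs —

    model parameter  ~ b0 + b1*diagnosis + b2*age + b3*gender + b4*education
    cognitive ability ~ b0 + b1*model parameter + b2*age + b3*gender + b4*education

— the diagnosis-by-parameter interaction model, Benjamini–Hochberg FDR
correction, and voxelwise FCS group contrasts.  Coding: diagnosis HC=0 /
aMCI=1, gender F=0 / M=1, so a negative diagnosis coefficient means the
patient group is lower.

OLS fits go through statsmodels; the chi-square and t-tests through scipy.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GROUP_CODES = {"HC": 0, "aMCI": 1}
GENDER_CODES = {"F": 0, "M": 1}
COVARIATES = ("age", "gender", "education")


def chi2_2x2(table, correction: bool = True) -> tuple[float, float]:
    """Two-tailed Pearson chi-square on a 2x2 count table (df=1), with the
    Yates continuity correction by default."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def two_sample_t(group1, group2, equal_var: bool = True) -> tuple[float, float]:
    """Two-tailed two-sample t-test (pooled variance by default; Welch with
    ``equal_var=False``).

    Each group is either a raw vector (array/list) or a ``(mean, sd, n)``
    summary *tuple*, so printed summary statistics can be tested directly.
    """
    def unpack(g):
        if isinstance(g, tuple) and len(g) == 3:
            m, s, n = float(g[0]), float(g[1]), int(g[2])
            if n < 2:
                raise ValueError("each group needs n >= 2 observations")
            return m, s, n
        g = np.asarray(g, dtype=float)
        if g.ndim != 1 or g.size < 2:
            raise ValueError("each group needs n >= 2 observations")
        return float(g.mean()), float(g.std(ddof=1)), int(g.size)

    m1, s1, n1 = unpack(group1)
    m2, s2, n2 = unpack(group2)
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return 0.0, 1.0
        raise ValueError("zero variance in both groups")
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    return float(t), float(p)


def demographics_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-variable group summaries and tests: chi-square for gender,
    pooled t for age, education, MMSE and MoCA."""
    hc = records[records["group"] == "HC"]
    am = records[records["group"] == "aMCI"]
    rows = [{"variable": "N", "HC": f"{len(hc)}", "aMCI": f"{len(am)}",
             "test": "", "p": np.nan}]
    tab = [[(hc["gender"] == "F").sum(), (hc["gender"] == "M").sum()],
           [(am["gender"] == "F").sum(), (am["gender"] == "M").sum()]]
    _, p = chi2_2x2(tab)
    rows.append({"variable": "gender (F/M)",
                 "HC": f"{tab[0][0]}/{tab[0][1]}", "aMCI": f"{tab[1][0]}/{tab[1][1]}",
                 "test": "chi2", "p": p})
    for var in ("age", "education", "mmse", "moca"):
        _, p = two_sample_t(hc[var].to_numpy(), am[var].to_numpy())
        rows.append({"variable": var,
                     "HC": f"{hc[var].mean():.1f} [{hc[var].std(ddof=1):.1f}]",
                     "aMCI": f"{am[var].mean():.1f} [{am[var].std(ddof=1):.1f}]",
                     "test": "t", "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GLMs
# ---------------------------------------------------------------------------


def _design(records: pd.DataFrame, extra: Mapping[str, np.ndarray] | None = None
            ) -> pd.DataFrame:
    X = pd.DataFrame({
        "const": 1.0,
        "diagnosis": records["group"].map(GROUP_CODES).astype(float).to_numpy(),
        "age": records["age"].astype(float).to_numpy(),
        "gender": records["gender"].map(GENDER_CODES).astype(float).to_numpy(),
        "education": records["education"].astype(float).to_numpy(),
    })
    if X[["diagnosis", "gender"]].isna().any().any():
        raise ValueError("unknown group or gender label in the cohort table")
    for name, col in (extra or {}).items():
        X[name] = np.asarray(col, dtype=float)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns by greedy elimination
        bad = []
        cols = list(X.columns)
        for c in cols:
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank:
                bad.append(c)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _ols_table(y: np.ndarray, X: pd.DataFrame, network: str = "") -> pd.DataFrame:
    _check_rank(X)
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return pd.DataFrame({
        "network": network,
        "term": X.columns,
        "estimate": res.params.to_numpy(),
        "t": res.tvalues.to_numpy(),
        "p_raw": res.pvalues.to_numpy(),
    })


def glm_group_difference(param: Sequence[float], records: pd.DataFrame,
                         network: str = "") -> pd.DataFrame:
    """OLS of a per-subject model parameter on diagnosis + age + gender +
    education; the ``diagnosis`` row carries the group contrast."""
    param = np.asarray(param, dtype=float)
    if len(param) != len(records):
        raise ValueError("parameter vector and cohort table must align")
    counts = records["group"].value_counts()
    if counts.min() < 5 or len(counts) != 2:
        raise ValueError("need >= 5 subjects in each of the two groups")
    return _ols_table(param, _design(records), network)


def glm_cognition(cognitive_ability: Sequence[float], param: Sequence[float],
                  records: pd.DataFrame, network: str = "",
                  group: str | None = "aMCI") -> pd.DataFrame:
    """OLS of cognitive ability on a model parameter + covariates; run
    within one diagnostic group (the patient group by default, where the
    association with cognition is probed)."""
    df = records.reset_index(drop=True)
    y = np.asarray(cognitive_ability, dtype=float)
    x = np.asarray(param, dtype=float)
    if len(y) != len(df) or len(x) != len(df):
        raise ValueError("inputs must align with the cohort table")
    if group is not None:
        sel = (df["group"] == group).to_numpy()
        if sel.sum() < 5:
            raise ValueError(f"need >= 5 subjects in group {group!r}")
        df, y, x = df[sel], y[sel], x[sel]
    X = _design(df, extra={"param": x})
    X = X.drop(columns=["diagnosis"]) if group is not None else X
    out = _ols_table(y, X, network)
    return out


def interaction_model(cognitive_ability: Sequence[float], param: Sequence[float],
                      records: pd.DataFrame, network: str = "") -> pd.DataFrame:
    """Diagnosis-by-parameter interaction on cognitive ability, controlling
    for age, gender and education; the ``diagnosis:param`` row tests whether
    the parameter's slope differs between groups."""
    df = records.reset_index(drop=True)
    y = np.asarray(cognitive_ability, dtype=float)
    x = np.asarray(param, dtype=float)
    if len(y) != len(df) or len(x) != len(df):
        raise ValueError("inputs must align with the cohort table")
    if df["group"].nunique() != 2:
        raise ValueError("both diagnostic groups must be present")
    diag = df["group"].map(GROUP_CODES).astype(float).to_numpy()
    X = _design(df, extra={"param": x, "diagnosis:param": diag * x})
    return _ols_table(y, X, network)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def group_difference_table(params_by_network: Mapping[str, Sequence[float]],
                           records: pd.DataFrame) -> pd.DataFrame:
    """Per-network diagnosis GLMs with BH-FDR across networks.

    The FDR family is the set of networks tested at one threshold (the
    whole brain plus the seven subnetworks), corrected separately per
    threshold.
    """
    rows = [glm_group_difference(v, records, network=k)
            for k, v in params_by_network.items()]
    out = pd.concat(rows, ignore_index=True)
    _attach_fdr(out, "diagnosis")
    return out


def _attach_fdr(table: pd.DataFrame, term: str) -> None:
    """BH-adjust the p-values of one term in place, across networks.
    Non-finite p-values (saturated fits) are left NaN rather than adjusted."""
    table["p_fdr"] = np.nan
    sel = (table["term"] == term) & np.isfinite(table["p_raw"])
    if sel.any():
        table.loc[sel, "p_fdr"] = bh_fdr(table.loc[sel, "p_raw"].to_numpy())


def cognition_table(params_by_network: Mapping[str, Sequence[float]],
                    cognitive_ability: Sequence[float],
                    records: pd.DataFrame, group: str = "aMCI") -> pd.DataFrame:
    """Per-network cognition GLMs (within one group) with BH-FDR across
    networks on the parameter slope."""
    rows = [glm_cognition(cognitive_ability, v, records, network=k, group=group)
            for k, v in params_by_network.items()]
    out = pd.concat(rows, ignore_index=True)
    _attach_fdr(out, "param")
    return out


def fcs_group_map(fcs_maps: np.ndarray, records: pd.DataFrame) -> pd.DataFrame:
    """Voxelwise two-group contrast of FCS maps, controlling for age,
    gender and education, with BH-FDR across voxels.

    ``fcs_maps`` is (n_subjects, n_voxels), voxel-aligned across subjects.
    Returns one row per voxel: t, p_raw, p_fdr for the diagnosis term.
    """
    Y = np.asarray(fcs_maps, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != len(records):
        raise ValueError("fcs_maps must be (n_subjects, n_voxels) aligned "
                         "with the cohort table")
    X = _design(records)
    _check_rank(X)
    Xm = X.to_numpy()
    n, k = Xm.shape
    XtX_inv = np.linalg.inv(Xm.T @ Xm)
    beta = XtX_inv @ (Xm.T @ Y)                      # (k, n_voxels)
    resid = Y - Xm @ beta
    dof = n - k
    sigma2 = np.sum(resid**2, axis=0) / dof
    j = list(X.columns).index("diagnosis")
    # voxels fitted exactly (zero residual variance relative to the data
    # scale) have no group effect: t = 0 rather than float-noise 0/0
    exact = sigma2 <= 1e-24 * np.maximum(1.0, np.mean(Y**2, axis=0))
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[j, j], 1e-300))
    t = np.where(exact, 0.0, beta[j] / se)
    p_raw = 2.0 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame({"voxel": np.arange(Y.shape[1]), "t": t,
                         "p_raw": p_raw, "p_fdr": bh_fdr(p_raw)})
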