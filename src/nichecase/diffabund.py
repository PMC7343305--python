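"""Differential carriage and abundance signals.

Two complementary tests for case association per ASV:

* ``prevalence_regression`` — prevalence ratios (PRs) for carriage of each
  ASV, from a log-binomial model approximated by Poisson regression with
  robust (sandwich) standard errors, adjusted for the study covariates.
* ``ancom_modified`` — a covariate-adjusted ANCOM: every pairwise
  log-ratio log((c_i+1)/(c_j+1)) is regressed on case status plus
  covariates by OLS, the per-pair status p-values are BH-corrected, and
  each feature's W is the fraction of its comparisons that remain
  significant; W >= 0.8 flags differential abundance.

The pairwise OLS step is vectorized: with a common design matrix X, the
coefficients of y = L_i - L_j equal the difference of the per-feature
coefficients, and the pair RSS comes from the residual cross-product
matrix, so no explicit loop over the O(k²) pairs is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import build_design
from .prep import PresenceMatrix
from .tables_io import FeatureTable

__all__ = ["prevalence_regression", "ancom_modified", "bh_adjust", "AncomResult"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs pass through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def prevalence_regression(
    presence: PresenceMatrix,
    metadata: pd.DataFrame,
    covariates: list[str] = ("age", "sex", "run", "smoking", "community", "teeth"),
    status_term: str = "status",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Adjusted prevalence ratio of each feature for cases vs controls.

    Fits, per feature, a Poisson GLM of the presence indicator on status
    plus covariates with a log link and HC0 sandwich variance — the
    standard robust-Poisson approximation to log-binomial regression,
    whose exponentiated status coefficient is the prevalence ratio.
    Features with constant presence are skipped. BH correction is applied
    across features; ``significant`` marks q < alpha.
    """
    meta = metadata.loc[presence.data.index]
    terms = [status_term] + [c for c in covariates if c in meta.columns]
    X = build_design(meta, terms)
    status_cols = [c for c in X.columns if c.startswith(f"{status_term}_")]
    if len(status_cols) != 1:
        raise ValueError(f"status term must be binary; got columns {status_cols}")
    s_idx = X.columns.get_loc(status_cols[0])
    Xv = X.to_numpy(dtype=float)

    rows = []
    for fid in presence.data.columns:
        y = presence.data[fid].to_numpy(dtype=float)
        if y.min() == y.max():
            rows.append((fid, np.nan, np.nan, np.nan, np.nan, "constant"))
            continue
        try:
            res = sm.GLM(y, Xv, family=sm.families.Poisson()).fit(cov_type="HC0")
        except Exception:
            rows.append((fid, np.nan, np.nan, np.nan, np.nan, "failed"))
            continue
        b, se = res.params[s_idx], res.bse[s_idx]
        note = "" if getattr(res, "converged", True) else "not_converged"
        rows.append(
            (fid, np.exp(b), np.exp(b - 1.96 * se), np.exp(b + 1.96 * se), res.pvalues[s_idx], note)
        )
    out = pd.DataFrame(
        rows, columns=["feature_id", "PR", "ci_low", "ci_high", "p_value", "note"]
    ).set_index("feature_id")
    out["q_value"] = bh_adjust(out["p_value"])
    out["significant"] = out["q_value"] < alpha
    return out


@dataclass
class AncomResult:
    """Per-feature ANCOM output: W in [0, 1], direction, significance."""

    table: pd.DataFrame
    critical_w: float
    #: status p-value per ordered feature pair (NaN where skipped)
    pairwise_p: pd.DataFrame

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def ancom_modified(
    table: FeatureTable,
    metadata: pd.DataFrame,
    covariates: list[str] = ("age", "sex", "run", "smoking", "community", "teeth"),
    status_term: str = "status",
    critical_w: float = 0.8,
    alpha: float = 0.05,
    bh_scope: str = "per_feature",
    denominator: str = "k_minus_1",
) -> AncomResult:
    """Covariate-adjusted ANCOM W statistic per feature.

    Counts are offset by 1 before the log-ratio. ``bh_scope`` controls
    whether BH runs within each feature's k-1 comparisons (default) or
    over the global pool of pairs; ``denominator`` normalizes W by the
    comparisons actually made per feature (``k_minus_1``, adjusted for
    skipped constant ratios) or by ``k``.
    """
    k = table.data.shape[1]
    if k < 3:
        raise ValueError("ANCOM needs at least 3 features")
    meta = metadata.loc[table.data.index]
    terms = [status_term] + [c for c in covariates if c in meta.columns]
    X = build_design(meta, terms)
    status_cols = [c for c in X.columns if c.startswith(f"{status_term}_")]
    if len(status_cols) != 1:
        raise ValueError(f"status term must be binary; got columns {status_cols}")
    s_idx = X.columns.get_loc(status_cols[0])
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if n <= p:
        raise ValueError("more design columns than samples")

    L = np.log(table.counts + 1.0)
    pinv = np.linalg.pinv(Xv)
    B = pinv @ L  # p x k per-feature coefficients
    E = L - Xv @ B
    cross = E.T @ E

    # pairwise status coefficient and RSS from per-feature pieces
    coef = B[s_idx][:, None] - B[s_idx][None, :]
    rss = np.diag(cross)[:, None] + np.diag(cross)[None, :] - 2 * cross
    rss = np.maximum(rss, 0.0)

    xtx_inv_ss = (pinv @ pinv.T)[s_idx, s_idx]
    dof = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof * xtx_inv_ss)
        tstat = coef / se
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)

    # a constant log-ratio carries no information: skip the comparison
    lr_var = np.diag(cross)[:, None] + np.diag(cross)[None, :] - 2 * cross
    centered = L - L.mean(axis=0)
    total_var = (
        (centered**2).sum(axis=0)[:, None]
        + (centered**2).sum(axis=0)[None, :]
        - 2 * centered.T @ centered
    )
    skipped = total_var <= 1e-12 * n
    np.fill_diagonal(skipped, True)
    pvals[skipped] = np.nan
    coef[skipped] = np.nan
    del lr_var

    if bh_scope == "per_feature":
        q = np.vstack([bh_adjust(pvals[i]) for i in range(k)])
    elif bh_scope == "global":
        iu = np.triu_indices(k, 1)
        q_flat = bh_adjust(pvals[iu])
        q = np.full((k, k), np.nan)
        q[iu] = q_flat
        q[(iu[1], iu[0])] = q_flat
    else:
        raise ValueError(f"unknown bh_scope {bh_scope!r}")

    n_sig = np.nansum(q < alpha, axis=1).astype(float)
    n_made = (~skipped).sum(axis=1).astype(float)
    if denominator == "k_minus_1":
        denom = np.where(n_made > 0, n_made, np.nan)
    elif denominator == "k":
        denom = float(k)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    W = n_sig / denom

    mean_coef = np.nanmean(np.where(skipped, np.nan, coef), axis=1)
    direction = np.where(
        mean_coef > 0, "case", np.where(mean_coef < 0, "control", "none")
    )
    out = pd.DataFrame(
        {
            "W": W,
            "direction": direction,
            "mean_status_coef": mean_coef,
            "n_comparisons": n_made.astype(int),
            "significant": W >= critical_w,
        },
        index=pd.Index(table.feature_ids, name="feature_id"),
    )
    pair_p = pd.DataFrame(pvals, index=table.feature_ids, columns=table.feature_ids)
    return AncomResult(out, critical_w, pair_p)
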