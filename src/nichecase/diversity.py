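"""Alpha/beta diversity, adjusted PERMANOVA, dispersion, Mantel, and PCoA.

Alpha metrics are observed ASVs, Shannon entropy in bits, and Faith's
phylogenetic diversity (including the stem path to the root). Beta
metrics are Bray-Curtis and unweighted / (unnormalized) weighted UniFrac
on rarefied counts. PERMANOVA is the sequential (Type-I) multi-term
partitioning of a Gower-centered distance matrix — the adonis model of
vegan — with free permutation of sample labels; covariates are listed
first and disease status last so its R² is the adjusted, incremental
share. Dispersion (permdisp with the centroid estimate), the Mantel
test, and PCoA are delegated to scikit-bio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.linalg import matrix_rank
from skbio import DistanceMatrix as SkbioDM
from skbio.diversity import alpha_diversity, beta_diversity
from skbio.stats.distance import mantel as _skbio_mantel
from skbio.stats.distance import permdisp as _skbio_permdisp
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .design import build_design, term_matrix
from .tables_io import FeatureTable, ValidationError, check_tree_coverage

__all__ = [
    "alpha_metrics",
    "z_normalize",
    "fit_alpha_model",
    "bray_curtis",
    "unifrac",
    "pcoa",
    "adonis",
    "permdisp",
    "mantel",
    "permutation_t_test",
    "group_distance_summary",
]

ALPHA_METRICS = ("observed", "shannon", "faith_pd")


def _as_table(table) -> FeatureTable:
    return table.table if hasattr(table, "table") else table


# ---------------------------------------------------------------------------
# alpha diversity


def alpha_metrics(rarefied_table, tree=None) -> pd.DataFrame:
    """Per-sample observed ASVs, Shannon (bits), and Faith PD.

    Faith PD requires ``tree`` and is the total branch length of the
    minimal subtree spanning the root and all present tips; it is omitted
    (all-NaN) when no tree is given.
    """
    table = _as_table(rarefied_table)
    counts = table.counts
    ids = table.sample_ids
    out = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    out["observed"] = (counts > 0).sum(axis=1)
    out["shannon"] = alpha_diversity("shannon", counts, ids=ids, base=2).to_numpy()
    if tree is not None:
        check_tree_coverage(tree, table.feature_ids)
        out["faith_pd"] = alpha_diversity(
            "faith_pd", counts, ids=ids, taxa=table.feature_ids, tree=tree
        ).to_numpy()
    else:
        out["faith_pd"] = np.nan
    return out


def z_normalize(alpha: pd.DataFrame, control_mask) -> pd.DataFrame:
    """Z-score each metric against the control mean and SD."""
    mask = np.asarray(control_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("need at least 2 controls")
    controls = alpha.loc[mask]
    mu, sd = controls.mean(axis=0), controls.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"zero control variance for {bad}")
    return (alpha - mu) / sd


def fit_alpha_model(
    alpha: pd.Series,
    metadata: pd.DataFrame,
    base_terms: list[str] = ("age", "sex", "run"),
    candidate_terms: list[str] = (),
) -> dict:
    """OLS model of one alpha metric with AIC forward selection.

    Base terms are always in the model. Candidates are added greedily
    while AIC strictly decreases. Each covariate's contribution is the
    leave-one-out drop in R²: R²(full) − R²(full without that term). A
    Jarque-Bera residual-normality p-value is included as a diagnostic.
    """
    y = np.asarray(alpha, dtype=float)

    def fit(terms):
        X = build_design(metadata, list(terms))
        if matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(f"rank-deficient design for terms {list(terms)}")
        return sm.OLS(y, X).fit()

    selected = list(base_terms)
    current = fit(selected)
    remaining = [t for t in candidate_terms if t not in selected]
    while remaining:
        trials = {t: fit(selected + [t]) for t in remaining}
        best = min(trials, key=lambda t: trials[t].aic)
        if trials[best].aic < current.aic:
            selected.append(best)
            current = trials[best]
            remaining.remove(best)
        else:
            break

    contributions = {}
    for term in selected:
        reduced = [t for t in selected if t != term]
        r2_reduced = fit(reduced).rsquared if reduced else 0.0
        contributions[term] = current.rsquared - r2_reduced
    jb_p = float(sm.stats.jarque_bera(current.resid)[1])
    return {
        "terms": selected,
        "model": current,
        "aic": float(current.aic),
        "r_squared": float(current.rsquared),
        "contributions": contributions,
        "residual_normality_p": jb_p,
    }


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(rarefied_table) -> SkbioDM:
    table = _as_table(rarefied_table)
    if (table.depths() == 0).any():
        raise ValidationError("zero-sum sample")
    return beta_diversity("braycurtis", table.counts, ids=table.sample_ids)


def unifrac(rarefied_table, tree, weighted: bool = False, normalized: bool = False) -> SkbioDM:
    """Unweighted or (by default unnormalized) weighted UniFrac."""
    table = _as_table(rarefied_table)
    check_tree_coverage(tree, table.feature_ids)
    if weighted:
        return beta_diversity(
            "weighted_unifrac",
            table.counts,
            ids=table.sample_ids,
            taxa=table.feature_ids,
            tree=tree,
            normalized=normalized,
        )
    return beta_diversity(
        "unweighted_unifrac",
        table.counts,
        ids=table.sample_ids,
        taxa=table.feature_ids,
        tree=tree,
    )


def pcoa(distance: SkbioDM):
    """Principal-coordinates analysis; negative eigenvalues are reported
    but excluded from the proportion-explained denominator."""
    return _skbio_pcoa(distance, method="eigh", warn_neg_eigval=False)


# ---------------------------------------------------------------------------
# PERMANOVA (adonis)


def _gower_center(dist: np.ndarray) -> np.ndarray:
    a = -0.5 * dist**2
    row = a.mean(axis=1, keepdims=True)
    return a - row - row.T + a.mean()


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


@dataclass
class AdonisResult:
    """Sequential PERMANOVA table: one row per term plus Residual/Total."""

    table: pd.DataFrame
    n_permutations: int

    def __str__(self) -> str:  # pragma: no cover - display helper
        return self.table.to_string()


def adonis(
    distance: SkbioDM,
    metadata: pd.DataFrame,
    formula_terms: list[str],
    n_perm: int = 9999,
    seed: int | None = None,
) -> AdonisResult:
    """Multi-term PERMANOVA with sequential (Type-I) sums of squares.

    Terms partition the total SS in the order given, so put adjustment
    covariates first and the term of interest last. Permutation p-values
    permute sample labels freely and include the observed statistic:
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids = list(distance.ids)
    meta = metadata.loc[ids]
    n = len(ids)
    G = _gower_center(distance.data.astype(float))
    ss_total = np.trace(G)

    # cumulative hat matrices: intercept, then +term_1, +term_2, ...
    blocks = [np.ones((n, 1))]
    dfs, ranks, hats = [], [matrix_rank(blocks[0])], [_hat(blocks[0])]
    for term in formula_terms:
        blocks.append(term_matrix(meta, term).to_numpy(dtype=float))
        X = np.hstack(blocks)
        r = matrix_rank(X)
        dfs.append(r - ranks[-1])
        ranks.append(r)
        hats.append(_hat(X))
    # a term fully collinear with earlier ones adds 0 df and 0 SS; it is
    # kept in the table (F and p undefined) rather than rejected
    dfs = np.asarray(dfs, dtype=float)
    diffs = [hats[i + 1] - hats[i] for i in range(len(formula_terms))]
    resid_proj = np.eye(n) - hats[-1]
    df_resid = n - ranks[-1]

    def term_stats(Gmat):
        ss = np.array([float((d * Gmat).sum()) for d in diffs])
        ss_resid = float((resid_proj * Gmat).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(dfs > 0, (ss / np.where(dfs > 0, dfs, 1)) / (ss_resid / df_resid), np.nan)
        return ss, ss_resid, F

    ss, ss_resid, F_obs = term_stats(G)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(formula_terms))
    for _ in range(n_perm):
        idx = rng.permutation(n)
        Gp = G[np.ix_(idx, idx)]
        _, _, F_perm = term_stats(Gp)
        exceed += F_perm >= F_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    pvals[dfs == 0] = np.nan

    rows = []
    for i, term in enumerate(formula_terms):
        rows.append((term, int(dfs[i]), ss[i], ss[i] / ss_total, F_obs[i], pvals[i]))
    rows.append(("Residual", df_resid, ss_resid, ss_resid / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "sum_sq", "r_squared", "pseudo_F", "p_value"]
    ).set_index("term")
    return AdonisResult(table, n_perm)


def permdisp(
    distance: SkbioDM,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.Series:
    """Test equality of group dispersions around spatial centroids."""
    grouping = pd.Series(np.asarray(groups), index=list(distance.ids))
    sizes = grouping.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        small = sizes.index[sizes < 2].tolist()
        raise ValueError(f"groups with a single sample: {small}")
    return _skbio_permdisp(
        distance,
        grouping.to_numpy(),
        test="centroid",
        permutations=n_perm,
        seed=seed,
        warn_neg_eigval=False,
    )


def mantel(
    d1: SkbioDM,
    d2: SkbioDM,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "pearson",
) -> tuple[float, float, float]:
    """Mantel correlation between two distance matrices: (r, r², p)."""
    if list(d1.ids) != list(d2.ids):
        if set(d1.ids) != set(d2.ids):
            raise ValueError("distance matrices cover different samples")
        d2 = d2.filter(d1.ids)
    r, p, _n = _skbio_mantel(d1, d2, method=method, permutations=n_perm, seed=seed)
    return float(r), float(r) ** 2, float(p)


# ---------------------------------------------------------------------------
# group distance comparisons


def _within(dist, idx):
    sub = dist[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return sub[iu]


def _boot_ci(stat_fn, n_boot):
    stats = np.array([stat_fn() for _ in range(n_boot)])
    return float(np.percentile(stats, 2.5)), float(np.percentile(stats, 97.5))


def _perm_t(a_vals, b_vals):
    na, nb = len(a_vals), len(b_vals)
    va, vb = a_vals.var(ddof=1), b_vals.var(ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    if denom == 0:
        return 0.0
    return (a_vals.mean() - b_vals.mean()) / denom


def permutation_t_test(dist: np.ndarray, idx_a, idx_b, n_perm: int = 999, rng=None):
    """Permutational t-test for one group pair on a distance matrix.

    The statistic is a Welch t comparing between-group distances against
    the pooled within-group distances; the null redistributes the group
    labels over the pooled samples. Returns (t, p).
    """
    rng = np.random.default_rng(rng)
    idx_a, idx_b = np.asarray(idx_a), np.asarray(idx_b)
    pool = np.concatenate([idx_a, idx_b])
    na = len(idx_a)

    def t_for(positions_a):
        mask = np.zeros(len(pool), dtype=bool)
        mask[positions_a] = True
        pa, pb = pool[mask], pool[~mask]
        w = np.concatenate([_within(dist, pa), _within(dist, pb)])
        b = dist[np.ix_(pa, pb)].ravel()
        return _perm_t(b, w)

    t_obs = t_for(np.arange(na))
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pool))[:na]
        if abs(t_for(perm)) >= abs(t_obs):
            exceed += 1
    return t_obs, (1 + exceed) / (1 + n_perm)


def group_distance_summary(
    distance: SkbioDM,
    groups,
    n_boot: int = 1000,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Within/between-group mean distances with bootstrap CIs, plus
    pairwise permutational t-tests and pairwise PERMANOVA.

    The permutational t-test for a group pair compares between-group
    distances against the pooled within-group distances, with the null
    distribution generated by permuting sample-to-group labels. A group
    whose mean within-distance exceeds its mean distance to every other
    group is flagged ``heterogeneous``.
    """
    rng = np.random.default_rng(seed)
    ids = list(distance.ids)
    grouping = pd.Series(np.asarray(groups), index=ids)
    dist = distance.data
    levels = [g for g in pd.unique(grouping) if pd.notna(g)]
    index = {g: np.flatnonzero((grouping == g).to_numpy()) for g in levels}

    within = {}
    for g, idx in index.items():
        if len(idx) < 2:
            import warnings

            warnings.warn(f"group {g!r} has <2 members; within-distance skipped")
            continue
        vals = _within(dist, idx)
        lo, hi = _boot_ci(
            lambda: _within(dist, idx[rng.integers(0, len(idx), len(idx))]).mean(),
            n_boot,
        )
        within[g] = {"mean": float(vals.mean()), "ci": (lo, hi), "n_pairs": len(vals)}

    between, tests = {}, {}
    for i, g in enumerate(levels):
        for h in levels[i + 1 :]:
            ia, ib = index[g], index[h]
            cross = dist[np.ix_(ia, ib)].ravel()

            def boot():
                ra = ia[rng.integers(0, len(ia), len(ia))]
                rb = ib[rng.integers(0, len(ib), len(ib))]
                return dist[np.ix_(ra, rb)].mean()

            lo, hi = _boot_ci(boot, n_boot)
            between[(g, h)] = {"mean": float(cross.mean()), "ci": (lo, hi)}

            t_obs, t_p = permutation_t_test(dist, ia, ib, n_perm=n_perm, rng=rng)

            pool = np.concatenate([ia, ib])
            pair_ids = [ids[k] for k in pool]
            sub = SkbioDM(dist[np.ix_(pool, pool)], ids=pair_ids)
            sub_meta = pd.DataFrame({"group": grouping.loc[pair_ids]})
            ad = adonis(sub, sub_meta, ["group"], n_perm=n_perm, seed=int(rng.integers(2**31)))
            tests[(g, h)] = {
                "t": float(t_obs),
                "t_p": float(t_p),
                "permanova_p": float(ad.table.loc["group", "p_value"]),
                "permanova_r2": float(ad.table.loc["group", "r_squared"]),
            }

    heterogeneous = []
    for g in within:
        neighbors = [between[k]["mean"] for k in between if g in k]
        if neighbors and within[g]["mean"] > max(neighbors):
            heterogeneous.append(g)
    return {
        "within": within,
        "between": between,
        "tests": tests,
        "heterogeneous": heterogeneous,
    }
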