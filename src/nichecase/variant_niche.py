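"""Coexcluding two-variant (subspecies niche) analysis.

Given two single-nucleotide variants of one species (A and B), classify
each sample's carriage state (A only, B only, both, neither) at a
relative-abundance threshold, model state membership against case status
with multinomial logistic regression (A-only as reference), re-derive
community structure with the focal genus stripped out, and decompose how
much of the case-status community signal the variant term absorbs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .design import build_design
from .diffabund import bh_adjust
from .diversity import adonis, bray_curtis, mantel, unifrac
from .prep import PRESENCE_THRESHOLD, rarefy
from .tables_io import FeatureTable

__all__ = [
    "classify_carriage",
    "variant_log_ratio",
    "multinomial_carriage_model",
    "strip_genus_recompute",
    "attribute_variance",
    "variant_richness_test",
    "CARRIAGE_STATES",
]

#: Order fixes A_only as the multinomial reference level.
CARRIAGE_STATES = ("A_only", "both", "B_only", "neither")


def classify_carriage(
    table: FeatureTable,
    variant_a: str,
    variant_b: str,
    threshold: float = PRESENCE_THRESHOLD,
) -> pd.Series:
    """Per-sample carriage state of the two focal variants.

    Presence means relative abundance >= threshold. ``neither`` samples
    are excluded from downstream variant analyses by the callers.
    """
    for v in (variant_a, variant_b):
        if v not in table.data.columns:
            raise KeyError(f"variant {v!r} not in table")
    rel = table.relative_abundance()
    has_a = rel[variant_a] >= threshold
    has_b = rel[variant_b] >= threshold
    state = np.select(
        [has_a & has_b, has_a, has_b],
        ["both", "A_only", "B_only"],
        default="neither",
    )
    return pd.Series(
        pd.Categorical(state, categories=list(CARRIAGE_STATES)),
        index=table.data.index,
        name="carriage",
    )


def variant_log_ratio(
    table: FeatureTable,
    variant_a: str,
    variant_b: str,
    clip: float = 15.0,
) -> pd.DataFrame:
    """ln(rel_B / rel_A) per sample, for display.

    Single-carrier samples get the +/-clip sentinel (flagged ``clipped``);
    samples carrying neither variant are excluded. Modelling uses
    carriage states, never these clipped values.
    """
    if clip <= 0:
        raise ValueError("clip must be positive")
    rel = table.relative_abundance()
    a, b = rel[variant_a].to_numpy(), rel[variant_b].to_numpy()
    keep = (a > 0) | (b > 0)
    a, b = a[keep], b[keep]
    with np.errstate(divide="ignore"):
        ratio = np.log(b) - np.log(a)
    clipped = ~np.isfinite(ratio) | (np.abs(ratio) > clip)
    ratio = np.clip(ratio, -clip, clip)
    ratio[(b == 0)] = -clip
    ratio[(a == 0)] = clip
    return pd.DataFrame(
        {"log_ratio": ratio, "clipped": clipped},
        index=table.data.index[keep],
    )


@dataclass
class MultinomResult:
    """Odds ratios vs the A_only reference state, with Wald 95% CIs."""

    odds_ratios: pd.DataFrame
    coefficients: pd.DataFrame
    converged: bool
    separation_flag: bool


def multinomial_carriage_model(
    states: pd.Series,
    metadata: pd.DataFrame,
    covariates: list[str] = (),
    status_term: str = "status",
) -> MultinomResult:
    """Multinomial logit of carriage state on case status plus covariates.

    ``neither`` samples are dropped; A_only is the reference outcome.
    Returns per non-reference state the status odds ratio with Wald CI.
    Very large coefficients (|beta| > 15) raise the separation flag.
    """
    keep = states.notna() & (states != "neither")
    states = states[keep]
    observed = [s for s in CARRIAGE_STATES[:3] if (states == s).any()]
    if len(observed) < 2:
        raise ValueError(f"need >=2 non-empty carriage states, got {observed}")
    if "A_only" not in observed:
        raise ValueError("reference state A_only is empty")
    meta = metadata.loc[states.index]
    terms = [status_term] + [c for c in covariates if c in meta.columns]
    X = build_design(meta, terms)
    y = pd.Categorical(states.astype(str), categories=observed).codes

    model = sm.MNLogit(y, X.to_numpy(dtype=float))
    res = model.fit(method="newton", maxiter=200, disp=False)
    params = pd.DataFrame(res.params, index=X.columns, columns=observed[1:])
    bse = pd.DataFrame(res.bse, index=X.columns, columns=observed[1:])
    pv = pd.DataFrame(res.pvalues, index=X.columns, columns=observed[1:])

    status_cols = [c for c in X.columns if c.startswith(f"{status_term}_")]
    if len(status_cols) != 1:
        raise ValueError("status term must be binary")
    sc = status_cols[0]
    rows = []
    for state in observed[1:]:
        b, se = params.loc[sc, state], bse.loc[sc, state]
        rows.append(
            (state, np.exp(b), np.exp(b - 1.96 * se), np.exp(b + 1.96 * se), pv.loc[sc, state])
        )
    ors = pd.DataFrame(
        rows, columns=["state", "OR", "ci_low", "ci_high", "p_value"]
    ).set_index("state")
    separation = bool((np.abs(params.to_numpy()) > 15).any())
    return MultinomResult(ors, params, bool(res.mle_retvals["converged"]), separation)


def strip_genus_recompute(
    table: FeatureTable,
    genus_feature_ids: list[str],
    depth: int = 6250,
    tree=None,
    seed: int = 0,
    full_distances: dict | None = None,
    n_perm: int = 999,
) -> dict:
    """Remove a genus, re-rarefy, and recompute beta diversity.

    Returns the stripped-table distances (Bray-Curtis always; unweighted
    and weighted UniFrac when a tree is given) and, if ``full_distances``
    is supplied, Mantel comparisons of each stripped metric against its
    full-community counterpart on the shared samples.
    """
    genus_feature_ids = [f for f in genus_feature_ids]
    if not genus_feature_ids:
        raise ValueError("genus feature list is empty")
    present = [f for f in genus_feature_ids if f in table.data.columns]
    stripped = table.drop_features(present)
    if stripped.data.shape[1] == 0:
        raise ValueError("stripping removed every feature")
    rare = rarefy(stripped, depth, seed)

    distances: dict[str, object] = {"braycurtis": bray_curtis(rare)}
    if tree is not None:
        distances["unweighted_unifrac"] = unifrac(rare, tree, weighted=False)
        distances["weighted_unifrac"] = unifrac(rare, tree, weighted=True)

    report = {"distances": distances, "dropped_samples": rare.dropped, "mantel": {}}
    for name, dm in distances.items():
        if full_distances and name in full_distances:
            full = full_distances[name]
            shared = [s for s in dm.ids if s in set(full.ids)]
            r, r2, p = mantel(
                dm.filter(shared), full.filter(shared), n_perm=n_perm, seed=seed
            )
            report["mantel"][name] = {"r": r, "r_squared": r2, "p_value": p}
    return report


@dataclass
class VarianceAttribution:
    """Share of the status community signal explained by the variant."""

    r2_status_excluding: float
    r2_status_including: float
    proportion: float
    negative_flag: bool


def attribute_variance(
    distance,
    metadata: pd.DataFrame,
    covariates: list[str],
    status_term: str = "status",
    variant_term: str = "carriage",
    n_perm: int = 999,
    seed: int | None = None,
) -> VarianceAttribution:
    """How much of status's community R² the variant term absorbs.

    Two sequential PERMANOVA fits share covariates and end with status;
    the second inserts the variant term before status. The proportion is
    (R²_status_excluding − R²_status_including) / R²_status_excluding.
    A negative proportion is reported but flagged.
    """
    meta = metadata.loc[list(distance.ids)]
    if meta[variant_term].astype("object").nunique() < 2:
        raise ValueError(f"variant term {variant_term!r} has a single level")
    covs = [c for c in covariates if c in meta.columns]
    excl = adonis(distance, meta, covs + [status_term], n_perm=n_perm, seed=seed)
    incl = adonis(
        distance, meta, covs + [variant_term, status_term], n_perm=n_perm, seed=seed
    )
    r2_excl = float(excl.table.loc[status_term, "r_squared"])
    r2_incl = float(incl.table.loc[status_term, "r_squared"])
    prop = (r2_excl - r2_incl) / r2_excl if r2_excl > 0 else np.nan
    return VarianceAttribution(r2_excl, r2_incl, prop, bool(prop < 0))


def variant_richness_test(alpha: pd.DataFrame, states: pd.Series) -> pd.DataFrame:
    """Pairwise rank-sum tests of observed-ASV richness across carriage
    states, BH-corrected; states with fewer than 2 samples are excluded."""
    rich = alpha["observed"]
    states = states.loc[rich.index]
    groups = {}
    for s in CARRIAGE_STATES[:3]:
        vals = rich[(states == s).to_numpy()].to_numpy(dtype=float)
        if len(vals) >= 2:
            groups[s] = vals
    if len(groups) < 2:
        raise ValueError("need >=2 carriage states with >=2 samples")
    names = list(groups)
    rows = []
    for i, g in enumerate(names):
        for h in names[i + 1 :]:
            stat, p = sps.mannwhitneyu(groups[g], groups[h], alternative="two-sided")
            rows.append((g, h, float(np.median(groups[g])), float(np.median(groups[h])), stat, p))
    out = pd.DataFrame(
        rows, columns=["group_a", "group_b", "median_a", "median_b", "U", "p_value"]
    )
    out["q_value"] = bh_adjust(out["p_value"])
    return out
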