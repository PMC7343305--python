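"""Synthetic case-control ASV datasets with known ground truth.

The generator emulates the statistical structure of a case-control oral
16S study so every pipeline stage is testable without external data:

* a Dirichlet-multinomial count model over a lognormal rank-abundance
  baseline, with per-sample lognormal fluctuation of basis abundances;
* case status shifting a small set of truly enriched/depleted ASVs;
* smoking confounding (smoking correlates with case status and shifts
  its own set of ASVs);
* a coexcluding two-variant pair in one genus: each sample draws a
  carriage state (A only / both / B only / neither) from a group-specific
  mixture; in single-carrier samples the absent variant is a structural
  zero, so the present one dominates by construction (the >=50-fold
  dominance contract holds with an infinite ratio);
* a variant-niche community shift: carriage state tilts a block of
  background ASVs, so the variant structures the wider community;
* a planted positively correlated basis pair for network recovery;
* a random bifurcating phylogeny (exponential branch lengths) with the
  variant pair as sister tips, and per-ASV sequences in which the two
  variants differ at exactly one position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables_io import AsvRecord, FeatureTable

__all__ = ["SynthConfig", "SynthTruth", "generate_dataset", "paper_like_preset"]

_GENERA = [
    "Streptococcus", "Veillonella", "Prevotella", "Neisseria", "Haemophilus",
    "Rothia", "Actinomyces", "Fusobacterium", "Porphyromonas", "Leptotrichia",
    "Capnocytophaga", "Gemella", "Lautropia", "Corynebacterium", "Selenomonas",
    "Campylobacter", "Aggregatibacter", "Lactobacillus", "Abiotrophia", "Oribacterium",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SynthConfig:
    """All knobs of the generator; defaults come from ``paper_like_preset``."""

    n_cases: int = 500
    n_controls: int = 500
    k_features: int = 250
    depth_range: tuple = (5000, 20000)
    #: lognormal sigma of the rank-abundance baseline
    baseline_sigma: float = 1.5
    #: pin selected features' baseline relative abundance: index -> fraction
    baseline_overrides: dict = field(default_factory=dict)
    #: map feature index -> log-fold change in cases
    case_effects: dict = field(default_factory=dict)
    #: P(never, current, former) by group
    smoking_probs: dict = field(
        default_factory=lambda: {
            "case": (0.35, 0.55, 0.10),
            "control": (0.65, 0.25, 0.10),
        }
    )
    #: map feature index -> log-fold change in current smokers
    smoking_effects: dict = field(default_factory=dict)
    #: P(A_only, both, B_only, neither) by group
    carriage_probs: dict = field(
        default_factory=lambda: {
            "case": (0.230, 0.385, 0.380, 0.005),
            "control": (0.430, 0.305, 0.260, 0.005),
        }
    )
    #: guaranteed minimum abundance ratio in single-carrier samples;
    #: enforced structurally (the absent variant draws exactly zero)
    dominance_factor: float = 50.0
    #: total genus relative abundance carried by the variant pair
    genus_abundance: float = 0.030
    #: how the genus splits between A and B in the "both" state
    both_split: tuple = (0.4, 0.6)
    #: feature indices tilted by carriage state, and the tilt size (log scale)
    niche_features: tuple = ()
    niche_shift: float = 0.8
    #: per-feature per-sample lognormal noise (log-sd) of basis abundances
    log_noise_sd: float = 1.0
    #: planted correlated basis pairs: list of (i, j, rho)
    correlated_pairs: tuple = ()
    #: Dirichlet concentration (larger = less overdispersion)
    concentration: float = 200.0
    sequence_length: int = 150
    seed: int = 2020

    def validate(self) -> None:
        for group, probs in self.carriage_probs.items():
            if len(probs) != 4 or abs(sum(probs) - 1) > 1e-9 or min(probs) < 0:
                raise ValueError(f"carriage probabilities for {group} must be a 4-simplex")
        for group, probs in self.smoking_probs.items():
            if abs(sum(probs) - 1) > 1e-9 or min(probs) < 0:
                raise ValueError(f"smoking probabilities for {group} must sum to 1")
        if self.dominance_factor < 1:
            raise ValueError("dominance_factor must be >= 1")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth range")
        if self.k_features < 10:
            raise ValueError("need at least 10 features")


@dataclass
class SynthTruth:
    """Ground truth aligned with the emitted table ids."""

    case_effects: dict  # feature id -> true log-fold change in cases
    smoking_effects: dict
    carriage: pd.Series  # per-sample true carriage state
    covariates: pd.DataFrame
    correlated_pairs: list  # (feature id, feature id, rho)
    variant_a: str
    variant_b: str
    niche_features: list
    case_enriched: list  # ids with positive case effect
    control_enriched: list  # ids with negative case effect


def _random_tree(feature_ids, sister_pair, rng) -> TreeNode:
    """Random bifurcating topology, exponential(1) branch lengths; the
    ``sister_pair`` ids are pre-joined so they are guaranteed sisters."""
    def leaf(name):
        return TreeNode(name=name, length=float(rng.exponential(1.0)))

    a, b = sister_pair
    pair = TreeNode(length=float(rng.exponential(1.0)), children=[leaf(a), leaf(b)])
    nodes = [pair] + [leaf(f) for f in feature_ids if f not in sister_pair]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        merged = TreeNode(
            length=float(rng.exponential(1.0)), children=[nodes[i], nodes[j]]
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = nodes[0]
    root.length = None
    return root


def _sequences(config: SynthConfig, rng) -> list[str]:
    """One random sequence per feature; features 0 and 1 (the variant
    pair) differ at exactly one position."""
    seqs = [
        "".join(rng.choice(_BASES, size=config.sequence_length))
        for _ in range(config.k_features)
    ]
    var_a = list(seqs[0])
    pos = int(rng.integers(config.sequence_length))
    alternatives = [x for x in "ACGT" if x != var_a[pos]]
    var_b = var_a.copy()
    var_b[pos] = alternatives[int(rng.integers(3))]
    seqs[1] = "".join(var_b)
    return seqs


def generate_dataset(config: SynthConfig):
    """Draw a full synthetic study.

    Returns (FeatureTable, metadata DataFrame, tree, AsvRecord list,
    SynthTruth). Feature indices 0 and 1 are variant A and variant B.
    Deterministic for a fixed config (one RNG stream seeded by
    ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k, n = config.k_features, config.n_cases + config.n_controls

    # identities ------------------------------------------------------------
    seqs = _sequences(config, rng)
    genera = ["Granulicatella", "Granulicatella"] + [
        _GENERA[int(g)] for g in rng.integers(0, len(_GENERA), k - 2)
    ]
    records = [AsvRecord(sequence=s, taxonomy=[g]) for s, g in zip(seqs, genera)]
    feature_ids = []
    seen = set()
    for rec in records:  # de-duplicate display ids deterministically
        fid = rec.display_id
        while fid in seen:
            fid += "x"
        rec.display_id = fid
        seen.add(fid)
        feature_ids.append(fid)
    variant_a, variant_b = feature_ids[0], feature_ids[1]

    # baseline composition --------------------------------------------------
    baseline = np.exp(rng.normal(0.0, config.baseline_sigma, size=k))
    baseline[0] = baseline[1] = 0.0
    free_mass = 1.0 - config.genus_abundance
    if config.baseline_overrides:
        pinned = sum(config.baseline_overrides.values())
        if pinned >= free_mass:
            raise ValueError("baseline overrides exceed available mass")
        over_idx = np.array(sorted(config.baseline_overrides), dtype=int)
        rest = np.setdiff1d(np.arange(2, k), over_idx)
        baseline[rest] *= (free_mass - pinned) / baseline[rest].sum()
        for i in over_idx:
            baseline[i] = config.baseline_overrides[int(i)]
    else:
        baseline = baseline / baseline.sum() * free_mass

    # covariates ------------------------------------------------------------
    status = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    is_case = status == "case"
    smoking = np.empty(n, dtype=object)
    for group in ("case", "control"):
        m = status == group
        smoking[m] = rng.choice(
            ["never", "current", "former"], size=m.sum(), p=config.smoking_probs[group]
        )
    age = np.clip(rng.normal(47, 12, size=n), 18, 85).round(1)
    sex = rng.choice(["female", "male"], size=n)
    run = rng.choice(["run1", "run2", "run3"], size=n)
    community = rng.choice(["comm1", "comm2", "comm3", "comm4"], size=n)
    teeth = rng.choice(["0-5", "6-10", "11+"], size=n, p=[0.5, 0.3, 0.2])

    carriage = np.empty(n, dtype=object)
    state_names = ["A_only", "both", "B_only", "neither"]
    for group in ("case", "control"):
        m = status == group
        carriage[m] = rng.choice(
            state_names, size=m.sum(), p=config.carriage_probs[group]
        )

    sample_ids = [f"S{i:04d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "status": pd.Categorical(status, categories=["control", "case"]),
            "age": age,
            "sex": pd.Categorical(sex),
            "run": pd.Categorical(run),
            "smoking": pd.Categorical(smoking, categories=["never", "current", "former"]),
            "community": pd.Categorical(community),
            "teeth": pd.Categorical(teeth),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    meta["excluded"] = False

    # per-sample basis abundances -------------------------------------------
    log_mu = np.tile(np.log(baseline + 1e-300), (n, 1))
    for idx, lfc in config.case_effects.items():
        log_mu[is_case, idx] += lfc
    current = smoking == "current"
    for idx, lfc in config.smoking_effects.items():
        log_mu[current, idx] += lfc
    if config.niche_features:
        half = len(config.niche_features) // 2
        up = list(config.niche_features[:half])
        down = list(config.niche_features[half:])
        a_only = carriage == "A_only"
        b_only = carriage == "B_only"
        log_mu[np.ix_(a_only, up)] += config.niche_shift
        log_mu[np.ix_(a_only, down)] -= config.niche_shift
        log_mu[np.ix_(b_only, up)] -= config.niche_shift
        log_mu[np.ix_(b_only, down)] += config.niche_shift

    noise = rng.normal(0.0, config.log_noise_sd, size=(n, k))
    for i, j, rho in config.correlated_pairs:
        shared = rng.normal(0.0, config.log_noise_sd, size=n)
        rho = float(rho)
        noise[:, i] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise[:, i]
        noise[:, j] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise[:, j]
    basis = np.exp(log_mu + noise)
    basis[:, :2] = 0.0

    # variant pair by carriage state ----------------------------------------
    g = config.genus_abundance
    wa, wb = config.both_split
    scale = basis.sum(axis=1) / (1.0 - g)  # genus share is relative
    var = np.zeros((n, 2))
    var[carriage == "A_only", 0] = g
    var[carriage == "B_only", 1] = g
    var[carriage == "both", 0] = g * wa
    var[carriage == "both", 1] = g * wb
    basis[:, 0] = var[:, 0] * scale
    basis[:, 1] = var[:, 1] * scale
    comp = basis / basis.sum(axis=1, keepdims=True)

    # Dirichlet-multinomial counts ------------------------------------------
    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1, size=n)
    gam = rng.gamma(np.maximum(comp * config.concentration, 0.0))
    probs = gam / gam.sum(axis=1, keepdims=True)
    counts = np.empty((n, k), dtype=np.int64)
    for s in range(n):
        counts[s] = rng.multinomial(depths[s], probs[s])

    table = FeatureTable(
        pd.DataFrame(counts, index=meta.index, columns=pd.Index(feature_ids, name="feature_id"))
    )
    tree = _random_tree(feature_ids, (variant_a, variant_b), rng)
    truth = SynthTruth(
        case_effects={feature_ids[i]: v for i, v in config.case_effects.items()},
        smoking_effects={feature_ids[i]: v for i, v in config.smoking_effects.items()},
        carriage=pd.Series(carriage, index=meta.index, name="carriage"),
        covariates=meta.drop(columns=["excluded"]),
        correlated_pairs=[
            (feature_ids[i], feature_ids[j], rho) for i, j, rho in config.correlated_pairs
        ],
        variant_a=variant_a,
        variant_b=variant_b,
        niche_features=[feature_ids[i] for i in config.niche_features],
        case_enriched=[feature_ids[i] for i, v in config.case_effects.items() if v > 0],
        control_enriched=[feature_ids[i] for i, v in config.case_effects.items() if v < 0],
    )
    return table, meta, tree, records, truth


def paper_like_preset(
    n_cases: int = 500, n_controls: int = 500, k_features: int = 250, seed: int = 2020
) -> SynthConfig:
    """The default study-like configuration.

    Two strongly case-enriched common ASVs (log-fold change +1.6), 51
    control-enriched lower-prevalence ASVs (log-fold changes between
    ln 0.5 and ln 0.8, targeting prevalence ratios around 0.7-0.9), a
    coexcluding variant pair whose carriage mixture marginalizes to about
    (33, 32, 35)% A-only / B-only / both with case enrichment of the B
    variant, smoking confounding, a 20-ASV variant-niche block, and one
    planted basis correlation of 0.8.
    """
    rng = np.random.default_rng(seed + 7)  # effect placement, not data
    case_idx = [2, 3]
    control_idx = list(range(4, 55))
    niche = tuple(range(55, 75))
    smoke_idx = list(range(75, 85))
    corr_pair = (85, 86, 0.8)
    effects = {i: 1.6 for i in case_idx}
    effects.update({i: float(rng.uniform(np.log(0.5), np.log(0.8))) for i in control_idx})
    smoking_effects = {
        i: float(rng.choice([-0.8, 0.8])) for i in smoke_idx
    }
    overrides = {i: 6e-4 for i in case_idx}
    overrides.update({i: 4e-4 for i in control_idx})
    overrides.update({i: 5e-3 for i in niche})
    overrides.update({i: 2e-3 for i in smoke_idx})
    overrides.update({corr_pair[0]: 1e-2, corr_pair[1]: 1e-2})
    return SynthConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        k_features=k_features,
        baseline_overrides=overrides,
        case_effects=effects,
        smoking_effects=smoking_effects,
        niche_features=niche,
        correlated_pairs=(corr_pair,),
        seed=seed,
    )
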