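"""Synthetic annotated-variant datasets with realistic missingness structure.

Real pathogenicity-annotation tables have a very particular shape: tens of
numeric tool scores whose *applicability* depends on the predicted molecular
consequence of the variant (protein-level scores are undefined for intronic
variants, splice-distance features are complete only at splice sites, ...),
producing block-structured missingness, very few complete cases, correlated
feature pairs, near-constant annotations, and *informative* missingness —
the fact that a value is absent is itself predictive of pathogenicity,
negatively for most features and positively for a few (population allele
frequencies are preferentially absent for pathogenic variants).

This module emulates exactly that structure so that every downstream stage
(preprocessing, amputation, imputation, classification, evaluation) can be
exercised without any external download:

* numeric features are Gaussian combinations of shared latent factors with
  consequence-class-dependent shifts, plus noise (feature correlations and
  class structure, not the marginal distributions of any real tool);
* structural missingness is applied per (consequence class, feature)
  according to an applicability table, then MCAR missingness on the
  remaining cells (overlaps counted once);
* the outcome is drawn from a logistic model over the *complete* values and
  the missingness indicators, so informative missingness exists by
  construction;
* everything is reproducible byte-for-byte from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import Dataset, FeatureTable

__all__ = [
    "OutcomeModel",
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "default_test_config",
    "DEFAULT_CONSEQUENCE_CLASSES",
    "write_ground_truth",
]

# Consequence vocabulary mirroring predicted molecular effect categories.
DEFAULT_CONSEQUENCE_CLASSES: tuple[tuple[str, float], ...] = (
    ("NON-SYNONYMOUS", 0.40),
    ("INTRONIC", 0.20),
    ("SPLICE_SITE", 0.10),
    ("UPSTREAM", 0.08),
    ("DOWNSTREAM", 0.08),
    ("INFRAME", 0.05),
    ("5PRIME_UTR", 0.05),
    ("NON-CODING_CHANGE", 0.04),
)


@dataclass
class OutcomeModel:
    """Logistic outcome model: intercept + values + missingness indicators.

    ``target_positive_rate``, when set, solves an additional intercept offset
    so the mean Bernoulli probability over the generated cohort equals the
    requested positive fraction.  Features listed in ``hinge_features``
    contribute ``coef * max(value, 0)`` (saturating response: conservation
    scores only carry signal in part of their range); features listed in
    ``magnitude_features`` contribute ``coef * |value|`` (signed change
    scores whose magnitude, not direction, is damaging — e.g. a hydrophobicity
    or stability change, or distance from a splice site).
    """

    intercept: float
    coefficients: pd.Series
    indicator_coefficients: pd.Series
    target_positive_rate: float | None = None
    hinge_features: tuple[str, ...] = ()
    magnitude_features: tuple[str, ...] = ()


@dataclass
class GeneratorConfig:
    n_variants: int
    consequence_classes: tuple[tuple[str, float], ...]
    feature_names: tuple[str, ...]
    applicability: pd.DataFrame  # (class x feature) structural-missingness probability
    mcar_rate: float
    outcome: OutcomeModel
    latent_factors: int = 5
    latent_loading_scale: float = 0.6
    class_shift_scale: float = 0.5
    n_near_constant: int = 2
    near_constant_rate: float = 0.003
    n_duplicate_pairs: int = 2
    duplicate_noise_sd: float = 0.08
    categorical_missing_rates: dict = field(
        default_factory=lambda: {"domain_class": 0.07, "regulatory_region": 0.05}
    )
    seed: int = 0

    @property
    def class_names(self) -> list[str]:
        return [name for name, _ in self.consequence_classes]

    @property
    def duplicate_sources(self) -> list[str]:
        return list(self.feature_names[: self.n_duplicate_pairs])

    @property
    def all_numeric_features(self) -> list[str]:
        dups = [f"{src}_dup" for src in self.duplicate_sources]
        ncs = [f"nearconst_{i}" for i in range(self.n_near_constant)]
        return list(self.feature_names) + dups + ncs

    def validate(self) -> None:
        props = np.array([p for _, p in self.consequence_classes], dtype=float)
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("consequence proportions must sum to 1")
        if (props <= 0).any():
            raise ValueError("degenerate config: consequence class with proportion 0")
        if not ((self.applicability.to_numpy() >= 0) & (self.applicability.to_numpy() <= 1)).all():
            raise ValueError("applicability probabilities must lie in [0, 1]")
        if not 0 <= self.mcar_rate <= 1:
            raise ValueError("mcar_rate must lie in [0, 1]")
        missing_rows = set(self.class_names) - set(self.applicability.index)
        if missing_rows:
            raise ValueError(f"applicability lacks classes {sorted(missing_rows)}")


@dataclass(eq=False)
class GroundTruth:
    """Pre-amputation values and outcome probabilities behind a generated dataset."""

    complete_values: pd.DataFrame
    outcome_probabilities: pd.Series
    config: GeneratorConfig


def _variant_ids(rng: np.random.Generator, n: int) -> pd.Index:
    chroms = rng.integers(1, 23, size=n)
    positions = 100000 + np.cumsum(rng.integers(1, 1000, size=n))
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n)]
    alt_shift = rng.integers(1, 4, size=n)
    alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]
    ids = [f"{c}:{p}:{r}:{a}" for c, p, r, a in zip(chroms, positions, ref, alt)]
    return pd.Index(ids, name="variant_id")


def generate(config: GeneratorConfig) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset (and its ground truth) from the configured process."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    names = config.class_names
    props = [p for _, p in config.consequence_classes]

    class_idx = rng.choice(len(names), size=n, p=props)
    labels = np.array(names, dtype=object)[class_idx]

    # Latent-factor numeric features with class-dependent shifts.
    core_names = list(config.feature_names)
    p_core = len(core_names)
    L = config.latent_factors
    z = rng.normal(size=(n, L))
    loadings = rng.normal(scale=config.latent_loading_scale / np.sqrt(L), size=(p_core, L))
    shifts = rng.normal(scale=config.class_shift_scale, size=(len(names), L))
    noise_sd = np.sqrt(max(1.0 - config.latent_loading_scale**2, 0.1))
    core = (z + shifts[class_idx]) @ loadings.T + rng.normal(scale=noise_sd, size=(n, p_core))

    columns: dict[str, np.ndarray] = {name: core[:, j] for j, name in enumerate(core_names)}
    for src in config.duplicate_sources:
        columns[f"{src}_dup"] = columns[src] + rng.normal(scale=config.duplicate_noise_sd, size=n)
    for i in range(config.n_near_constant):
        vals = np.zeros(n)
        hits = rng.random(n) < config.near_constant_rate
        vals[hits] = rng.integers(1, 4, size=int(hits.sum())).astype(float)
        columns[f"nearconst_{i}"] = vals

    all_names = config.all_numeric_features
    ids = _variant_ids(rng, n)
    complete = pd.DataFrame({name: columns[name] for name in all_names}, index=ids)

    # Structural (applicability-driven) missingness, then MCAR on what remains.
    applic = config.applicability.reindex(index=names, columns=all_names).fillna(0.0)
    per_row_applic = applic.to_numpy()[class_idx]
    structural = rng.random((n, len(all_names))) < per_row_applic
    mcar = rng.random((n, len(all_names))) < config.mcar_rate
    mask = structural | mcar

    # Outcome from complete values plus missingness indicators.
    coefs = config.outcome.coefficients.reindex(all_names).fillna(0.0).to_numpy()
    ind_coefs = config.outcome.indicator_coefficients.reindex(all_names).fillna(0.0).to_numpy()
    value_part = complete.to_numpy().copy()
    for feat in config.outcome.hinge_features:
        j = all_names.index(feat)
        value_part[:, j] = np.maximum(value_part[:, j], 0.0)
    for feat in config.outcome.magnitude_features:
        j = all_names.index(feat)
        value_part[:, j] = np.abs(value_part[:, j])
    linear = value_part @ coefs + mask.astype(float) @ ind_coefs
    offset = 0.0
    if config.outcome.target_positive_rate is not None:
        rate = config.outcome.target_positive_rate
        offset = brentq(
            lambda b: float(expit(config.outcome.intercept + b + linear).mean()) - rate,
            -60.0,
            60.0,
        )
    probs = expit(config.outcome.intercept + offset + linear)
    outcome = pd.Series(rng.binomial(1, probs), index=ids, name="outcome")

    observed = complete.where(~mask)

    # Three categorical features; the consequence label itself is one of them.
    cat = pd.DataFrame(index=ids)
    cat["consequence_class"] = labels
    cat["domain_class"] = rng.choice(np.array(list("ABCD"), dtype=object), size=n, p=[0.4, 0.3, 0.2, 0.1])
    cat["regulatory_region"] = rng.choice(
        np.array(["promoter", "enhancer", "none"], dtype=object), size=n, p=[0.2, 0.2, 0.6]
    )
    for col, rate in config.categorical_missing_rates.items():
        if rate > 0:
            cat.loc[rng.random(n) < rate, col] = np.nan

    ds = Dataset(
        FeatureTable(observed, cat),
        outcome,
        pd.Series(labels, index=ids, name="consequence"),
    )
    gt = GroundTruth(complete, pd.Series(probs, index=ids, name="p_positive"), config)
    return ds, gt


# ---------------------------------------------------------------------------
# Default configuration: the study conditions for every scaled experiment.
# ---------------------------------------------------------------------------

_FEATURE_GROUPS: dict[str, list[str]] = {
    "conservation": [
        "phyloP", "phastCons", "GERP_RS", "SiPhy", "bStatistic",
        "priPhCons", "mamPhCons", "verPhyloP",
    ],
    "protein": [
        "SIFT_score", "Polyphen2_score", "MutationAssessor", "PROVEAN",
        "LRT_score", "FATHMM_score", "MutPred_score", "grantham",
        "aa_volume_change", "hydrophobicity_change", "domain_score",
        "stability_change", "interaction_score", "active_site_dist",
        "codon_usage_shift", "secondary_structure_change",
    ],
    "coding_position": ["cDNApos", "CDSpos", "relProtPos", "exon_number"],
    "splice": ["splice_site_dist", "splice_pred"],
    "regulatory": ["DNase_seq", "EncodeH3K27ac", "EncodetotalRNA_sum", "TFBS_overlap"],
    "mirna": ["mirSVR_score", "targetscan_score"],
    "allele_frequency": ["gnomAD_exomes_AF", "gnomAD_genomes_AF"],
}

# Structural-missingness probability of each group per consequence class.
# Protein/coding features are inapplicable to non-coding consequences; splice
# distance is complete at splice sites; miRNA scores are mostly unobserved
# everywhere; allele frequencies are absent for variants unseen in cohorts.
_NONCODING = ("INTRONIC", "UPSTREAM", "DOWNSTREAM", "5PRIME_UTR", "NON-CODING_CHANGE")

_APPLICABILITY_RULES: dict[str, dict[str, float]] = {
    "conservation": {"*": 0.02},
    "protein": {"NON-SYNONYMOUS": 0.02, "INFRAME": 0.3, "SPLICE_SITE": 0.7, "*": 1.0},
    "coding_position": {"NON-SYNONYMOUS": 0.02, "INFRAME": 0.05, "SPLICE_SITE": 0.5, "*": 1.0},
    "splice": {"SPLICE_SITE": 0.02, "NON-SYNONYMOUS": 0.45, "*": 0.6},
    "regulatory": {"*": 0.05},
    "mirna": {"*": 0.7},
    "allele_frequency": {"*": 0.3},
}

# Most of the learnable signal sits on feature groups that are observed in
# the classes where they apply (conservation, regulatory, splice); protein
# scores matter too but are invisible wherever they are structurally missing.
# Baseline (weak) coefficient per group; a handful of headline tool scores
# carry concentrated signal via the overrides below, mirroring how a few
# strong predictors dominate real annotation data.
_GROUP_COEFS = {
    "conservation": 0.30,
    "protein": 0.20,
    "coding_position": 0.15,
    "splice": 1.50,
    "regulatory": 0.60,
    "mirna": 0.20,
    "allele_frequency": -1.50,
}

# Saturating responses: conservation-style scores and open-chromatin signals
# only matter in part of their range.
_HINGE_FEATURES = tuple(_FEATURE_GROUPS["conservation"]) + ("DNase_seq", "EncodeH3K27ac")
# Magnitude responses: signed change scores and splice-site distance, where
# |value| carries the signal.
_MAGNITUDE_FEATURES = (
    "aa_volume_change",
    "hydrophobicity_change",
    "stability_change",
    "splice_site_dist",
    "EncodetotalRNA_sum",
    "TFBS_overlap",
)
# Per-feature overrides of the group coefficient (sign or strength).
_COEF_OVERRIDES = {
    "phyloP": 2.50,
    "phastCons": 2.00,
    "GERP_RS": 1.20,
    "SIFT_score": 1.60,
    "Polyphen2_score": 1.20,
    "MutationAssessor": 0.80,
    "aa_volume_change": 1.50,
    "hydrophobicity_change": 1.50,
    "stability_change": 1.50,
    "splice_site_dist": -3.00,  # far from a splice site -> benign
    "DNase_seq": 1.40,
    "EncodeH3K27ac": 1.00,
    "EncodetotalRNA_sum": 2.00,
    "TFBS_overlap": 1.50,
}

# Indicator coefficients: mostly negative (missing implies lower likelihood of
# pathogenicity), positive for allele frequencies (absence from population
# cohorts is linked to higher likelihood of pathogenicity).
_GROUP_INDICATOR_COEFS = {
    "conservation": 0.0,
    "protein": -0.18,
    "coding_position": -0.10,
    "splice": -0.08,
    "regulatory": 0.0,
    "mirna": -0.08,
    "allele_frequency": 1.2,
}


def default_test_config(seed: int = 0, n_variants: int = 3736) -> GeneratorConfig:
    """The default study conditions: ~3700 variants, 42 numeric + 3
    categorical features, consequence-block missingness, informative
    missingness, very few complete cases, positive fraction 1564/3736."""
    feature_names = tuple(f for group in _FEATURE_GROUPS.values() for f in group)
    group_of = {f: g for g, feats in _FEATURE_GROUPS.items() for f in feats}
    class_names = [name for name, _ in DEFAULT_CONSEQUENCE_CLASSES]

    applic = pd.DataFrame(0.0, index=class_names, columns=list(feature_names))
    for feat in feature_names:
        rules = _APPLICABILITY_RULES[group_of[feat]]
        for cls in class_names:
            applic.loc[cls, feat] = rules.get(cls, rules["*"])
    # Derived features: duplicates inherit their source's applicability.
    dup_sources = list(feature_names[:2])
    for src in dup_sources:
        applic[f"{src}_dup"] = applic[src]
    for i in range(2):
        applic[f"nearconst_{i}"] = 0.0

    coefs, ind_coefs = {}, {}
    for j, feat in enumerate(feature_names):
        group = group_of[feat]
        base = _GROUP_COEFS[group]
        if feat in _COEF_OVERRIDES:
            coefs[feat] = _COEF_OVERRIDES[feat]
        elif group in ("conservation", "allele_frequency") or feat in _HINGE_FEATURES:
            # Conservation is positively damaging, frequency protective.
            coefs[feat] = base
        else:
            # Remaining linear features alternate signs within their group.
            coefs[feat] = base if j % 2 == 0 else -base
        ind_coefs[feat] = _GROUP_INDICATOR_COEFS[group]

    outcome = OutcomeModel(
        intercept=0.0,
        coefficients=pd.Series(coefs),
        indicator_coefficients=pd.Series(ind_coefs),
        target_positive_rate=1564 / 3736,
        hinge_features=_HINGE_FEATURES,
        magnitude_features=_MAGNITUDE_FEATURES,
    )
    return GeneratorConfig(
        n_variants=n_variants,
        consequence_classes=DEFAULT_CONSEQUENCE_CLASSES,
        feature_names=feature_names,
        applicability=applic,
        mcar_rate=0.005,
        outcome=outcome,
        class_shift_scale=0.3,
        seed=seed,
    )


def write_ground_truth(gt: GroundTruth, prefix: str | Path) -> None:
    """Write complete values + outcome probabilities and a config echo."""
    prefix = Path(prefix)
    values = gt.complete_values.copy()
    values["p_positive"] = gt.outcome_probabilities
    values.to_csv(f"{prefix}_ground_truth.csv")
    cfg = gt.config
    echo = {
        "n_variants": cfg.n_variants,
        "consequence_classes": {name: float(p) for name, p in cfg.consequence_classes},
        "mcar_rate": cfg.mcar_rate,
        "latent_factors": cfg.latent_factors,
        "n_near_constant": cfg.n_near_constant,
        "n_duplicate_pairs": cfg.n_duplicate_pairs,
        "seed": cfg.seed,
        "target_positive_rate": cfg.outcome.target_positive_rate,
        "features": list(cfg.all_numeric_features),
    }
    import yaml

    with open(f"{prefix}_config.yaml", "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=False)
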