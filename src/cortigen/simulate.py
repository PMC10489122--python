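"""Synthetic cohorts with planted genotype effects on cortical morphometry.

No public imaging-genetics cohort with APOE/MAPT genotyping at ages 18-24
is deposited anywhere, so every downstream stage of this package is
exercised on simulated data whose statistical structure mirrors the
study design it targets: four genotype groups (neither risk allele,
APOE e4 only, MAPT rs242557 A only, both), demographic covariates, and
286 regional morphometry features (68 Desikan-Killiany cortical regions
x {area, thickness, curvature, folding index} + 14 subcortical volumes).

The generative model for a feature with per-region baseline ``b`` is::

    x = b + b * noise_sd * (covariate term + genotype shifts + eps)

with ``eps ~ N(0, 1)`` i.i.d.  All planted shifts are therefore
expressed in residual-standard-deviation units (Cohen's d per unit
covariate or per carrier flag), which keeps power calculations
independent of the wildly different physical scales of the metrics
(areas of thousands of mm^2 versus curvatures of ~0.1 mm^-1).

Regions belong to one of four morphological archetypes (medium/thick/
smooth, large/thin/smooth, small/thick/convoluted, medium/thin/
convoluted) so that profile clustering has recoverable planted
structure; the interaction term is restricted to a designated region
subset, by default the medium/thick/smooth archetype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import (
    CORTICAL_METRICS,
    CORTICAL_REGIONS,
    HEMISPHERES,
    all_feature_names,
    cortical_region_names,
    parse_feature_name,
)

COHORT_COLUMNS = ("participant_id", "apoe_pos", "mapt_pos", "age", "sex", "education", "tiv")

# Genotype cells in the order (apoe, mapt): (0,0), (1,0), (0,1), (1,1).
GROUP_FLAGS = ((0, 0), (1, 0), (0, 1), (1, 1))
DEFAULT_GROUP_SIZES = (83, 11, 34, 16)

# Morphological archetypes: baseline per-region means for the 4 cortical
# metrics (area mm^2, thickness mm, mean curvature mm^-1, folding index).
ARCHETYPE_PROFILES: tuple[dict[str, float], ...] = (
    {"area": 2500.0, "thickness": 2.90, "curvature": 0.115, "folding_index": 0.14},
    {"area": 4200.0, "thickness": 2.30, "curvature": 0.118, "folding_index": 0.15},
    {"area": 1300.0, "thickness": 2.85, "curvature": 0.155, "folding_index": 0.28},
    {"area": 2500.0, "thickness": 2.30, "curvature": 0.158, "folding_index": 0.29},
)

# Assignment of the 34 bilateral parcels to archetypes (both hemispheres
# of a parcel share an archetype).  Archetype 0 collects the temporal /
# insular / mid-frontal regions where the gene-gene interaction is planted.
ARCHETYPE_OF_PARCEL: dict[str, int] = {
    # 0: medium area, thick, smooth
    "superiortemporal": 0, "middletemporal": 0, "inferiortemporal": 0,
    "temporalpole": 0, "entorhinal": 0, "parahippocampal": 0,
    "fusiform": 0, "insula": 0, "caudalmiddlefrontal": 0,
    # 1: large area, thin, smooth
    "superiorfrontal": 1, "rostralmiddlefrontal": 1, "superiorparietal": 1,
    "inferiorparietal": 1, "lateraloccipital": 1, "precentral": 1,
    "postcentral": 1, "supramarginal": 1, "precuneus": 1,
    # 2: small area, thick, convoluted
    "frontalpole": 2, "medialorbitofrontal": 2, "lateralorbitofrontal": 2,
    "parsorbitalis": 2, "parstriangularis": 2, "parsopercularis": 2,
    "rostralanteriorcingulate": 2, "caudalanteriorcingulate": 2,
    "transversetemporal": 2,
    # 3: medium area, thin, convoluted
    "cuneus": 3, "pericalcarine": 3, "lingual": 3, "bankssts": 3,
    "isthmuscingulate": 3, "posteriorcingulate": 3, "paracentral": 3,
}

# Subcortical baseline volumes, mm^3 (single hemisphere, adult means).
SUBCORTICAL_BASELINES: dict[str, float] = {
    "thalamus": 7800.0,
    "caudate": 3700.0,
    "putamen": 5200.0,
    "pallidum": 1800.0,
    "hippocampus": 4200.0,
    "amygdala": 1700.0,
    "accumbens": 600.0,
}

TIV_REFERENCE = 1.45e6  # mm^3; volumes scale linearly with intracranial volume

_METRICS_ALL = CORTICAL_METRICS + ("volume",)


def _default_interaction_regions() -> tuple[str, ...]:
    return tuple(
        f"{h}_{p}" for h in HEMISPHERES for p in CORTICAL_REGIONS
        if ARCHETYPE_OF_PARCEL[p] == 0
    )


@dataclass(frozen=True)
class EffectConfig:
    """Planted-effect configuration for :func:`generate_features`.

    All effect dictionaries map a metric name (``area``, ``thickness``,
    ``curvature``, ``folding_index``, ``volume``) to a shift in residual
    standard deviations; metrics absent from a dictionary get 0.

    Parameters
    ----------
    main_effect_apoe, main_effect_mapt
        Standardised shift added to every carrier of the respective
        allele, all regions.  Defaults encode thinner, more convoluted
        cortex in carriers.
    interaction_effect
        Extra standardised shift applied only to carriers of *both*
        alleles and only in ``interaction_regions``.
    interaction_regions
        Hemisphere-qualified cortical region names receiving the
        interaction term; default is the medium/thick/smooth archetype.
    covariate_slopes
        metric -> (age, sex, education) slopes, residual sd per unit of
        the (centred) covariate.
    noise_sd
        Residual standard deviation as a fraction of the feature's
        baseline mean (coefficient of variation). Must be positive.
    """

    main_effect_apoe: dict[str, float] = field(
        default_factory=lambda: {"thickness": -0.3, "curvature": 0.3, "folding_index": 0.3}
    )
    main_effect_mapt: dict[str, float] = field(
        default_factory=lambda: {"thickness": -0.2, "curvature": 0.2, "folding_index": 0.2}
    )
    interaction_effect: dict[str, float] = field(
        default_factory=lambda: {"curvature": 0.5, "folding_index": 0.5}
    )
    interaction_regions: tuple[str, ...] = field(default_factory=_default_interaction_regions)
    covariate_slopes: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "thickness": (-0.10, 0.0, 0.0),
            "area": (0.0, 0.5, 0.0),
            "volume": (0.0, 0.5, 0.0),
        }
    )
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        known = set(cortical_region_names())
        unknown = [r for r in self.interaction_regions if r not in known]
        if unknown:
            raise ValueError(f"unknown region(s) in interaction subset: {unknown}")
        if not self.interaction_regions:
            raise ValueError("interaction region subset must be non-empty")
        for d in (self.main_effect_apoe, self.main_effect_mapt, self.interaction_effect):
            bad = set(d) - set(_METRICS_ALL)
            if bad:
                raise ValueError(f"unknown metric(s) in effect dict: {sorted(bad)}")

    def null(self) -> "EffectConfig":
        """Copy of this config with every planted effect removed."""
        return replace(
            self,
            main_effect_apoe={},
            main_effect_mapt={},
            interaction_effect={},
            covariate_slopes={},
        )


def generate_cohort(
    group_sizes: tuple[int, int, int, int] = DEFAULT_GROUP_SIZES,
    age_range: tuple[float, float] = (18.0, 24.0),
    seed: int | None = None,
    *,
    age_mean: float = 20.6,
    age_sd: float = 0.9,
    p_male: float = 0.41,
    tiv_mean: float = TIV_REFERENCE,
    tiv_sd: float = 1.2e5,
) -> pd.DataFrame:
    """Simulate participant demographics for the four genotype groups.

    ``group_sizes`` counts participants in the cells (APOE-/MAPT-),
    (APOE+/MAPT-), (APOE-/MAPT+), (APOE+/MAPT+), in that order.  Ages
    are drawn from a normal distribution truncated to ``age_range``;
    education is integer years in {12, 13, 14}; sex is coded 1 = male.

    Returns a DataFrame with columns ``participant_id, apoe_pos,
    mapt_pos, age, sex, education, tiv``, deterministic given ``seed``.
    """
    if len(group_sizes) != 4:
        raise ValueError("group_sizes must have exactly four entries")
    if any(int(n) != n or n < 0 for n in group_sizes):
        raise ValueError(f"group sizes must be non-negative integers, got {group_sizes}")
    lo, hi = age_range
    if not (lo < hi):
        raise ValueError(f"invalid age range {age_range}")

    rng = np.random.default_rng(seed)
    n = int(sum(group_sizes))
    apoe = np.concatenate([np.full(k, f[0], dtype=int) for k, f in zip(group_sizes, GROUP_FLAGS)])
    mapt = np.concatenate([np.full(k, f[1], dtype=int) for k, f in zip(group_sizes, GROUP_FLAGS)])

    # truncated-normal ages by rejection; falls back to uniform if the
    # requested window has negligible mass under N(age_mean, age_sd)
    age = np.empty(n)
    remaining = np.arange(n)
    for _ in range(200):
        draw = rng.normal(age_mean, age_sd, size=remaining.size)
        ok = (draw >= lo) & (draw <= hi)
        age[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
        if remaining.size == 0:
            break
    if remaining.size:
        age[remaining] = rng.uniform(lo, hi, size=remaining.size)

    sex = (rng.random(n) < p_male).astype(int)
    education = rng.choice([12, 13, 14], size=n, p=[0.65, 0.30, 0.05])
    tiv = np.abs(rng.normal(tiv_mean, tiv_sd, size=n))

    return pd.DataFrame(
        {
            "participant_id": [f"sub-{i:04d}" for i in range(n)],
            "apoe_pos": apoe,
            "mapt_pos": mapt,
            "age": age,
            "sex": sex,
            "education": education.astype(int),
            "tiv": tiv,
        }
    )


def baseline_for_feature(name: str) -> float:
    """Noise-free archetype baseline for a canonical feature column."""
    _, region, metric = parse_feature_name(name)
    if metric == "volume":
        return SUBCORTICAL_BASELINES[region]
    return ARCHETYPE_PROFILES[ARCHETYPE_OF_PARCEL[region]][metric]


def generate_features(
    cohort: pd.DataFrame,
    config: EffectConfig | None = None,
    *,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Simulate the 286-column feature matrix for a cohort.

    Each feature is its region's archetype baseline plus (in residual-sd
    units) covariate terms, genotype main effects, the double-carrier
    interaction term in the designated regions, and standard normal
    noise.  Subcortical volumes additionally scale linearly with the
    participant's total intracranial volume.  With ``noiseless=True``
    the Gaussian residual is omitted (the systematic terms remain),
    which is useful for exactness tests.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    config = config or EffectConfig()
    rng = np.random.default_rng(config.seed)

    names = all_feature_names()
    n = len(cohort)
    apoe = cohort["apoe_pos"].to_numpy(dtype=float)
    mapt = cohort["mapt_pos"].to_numpy(dtype=float)
    age_c = cohort["age"].to_numpy(dtype=float) - 20.6
    sex = cohort["sex"].to_numpy(dtype=float)
    edu_c = cohort["education"].to_numpy(dtype=float) - 12.4
    tiv_scale = cohort["tiv"].to_numpy(dtype=float) / TIV_REFERENCE

    interaction_set = set(config.interaction_regions)
    out = np.empty((n, len(names)))
    for j, name in enumerate(names):
        hemi, region, metric = parse_feature_name(name)
        base = baseline_for_feature(name)
        a_slope, s_slope, e_slope = config.covariate_slopes.get(metric, (0.0, 0.0, 0.0))
        shift = a_slope * age_c + s_slope * sex + e_slope * edu_c
        shift = shift + config.main_effect_apoe.get(metric, 0.0) * apoe
        shift = shift + config.main_effect_mapt.get(metric, 0.0) * mapt
        if metric != "volume" and f"{hemi}_{region}" in interaction_set:
            shift = shift + config.interaction_effect.get(metric, 0.0) * apoe * mapt
        if not noiseless:
            shift = shift + rng.standard_normal(n)
        values = base + base * config.noise_sd * shift
        if metric == "volume":
            values = values * tiv_scale
        out[:, j] = values

    return pd.DataFrame(out, columns=names, index=cohort.index)


def generate_archetype_profiles(
    n_regions: int = 68,
    n_archetypes: int = 4,
    separation: float = 4.0,
    within_sd: float = 1.0,
    n_dims: int = 4,
    seed: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw region profiles from well-separated archetype centres.

    A direct fixture for profile-clustering benchmarks: archetype
    centres are placed ``separation * within_sd`` apart along coordinate
    axes (pairwise distance at least that), and each region's profile is
    its centre plus isotropic N(0, within_sd^2) noise.  Returns the
    profiles (indexed by the canonical region names when
    ``n_regions == 68``) and the planted archetype labels.
    """
    rng = np.random.default_rng(seed)
    centres = np.zeros((n_archetypes, n_dims))
    for a in range(n_archetypes):
        centres[a, a % n_dims] = separation * within_sd * (1 + a // n_dims)
    labels = np.arange(n_regions) % n_archetypes
    profiles = centres[labels] + rng.normal(0.0, within_sd, size=(n_regions, n_dims))
    index = cortical_region_names() if n_regions == 68 else [f"region_{i}" for i in range(n_regions)]
    cols = list(CORTICAL_METRICS)[:n_dims] if n_dims <= 4 else [f"dim_{d}" for d in range(n_dims)]
    return pd.DataFrame(profiles, index=index, columns=cols), labels


def archetype_labels() -> pd.Series:
    """Planted archetype index for each of the 68 cortical regions."""
    regions = cortical_region_names()
    return pd.Series(
        [ARCHETYPE_OF_PARCEL[r.split("_", 1)[1]] for r in regions],
        index=regions,
        name="archetype",
    )
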