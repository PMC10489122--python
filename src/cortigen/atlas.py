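"""Desikan-Killiany atlas layout and canonical feature naming.

Every table produced or consumed by this package names its columns
``<hemi>_<region>_<metric>`` (lowercase, snake case), e.g.
``left_precuneus_thickness`` or ``right_hippocampus_volume``.  The fixed
ordering defined here makes feature matrices, SVM weight maps and cluster
assignments joinable by name.
"""

from __future__ import annotations

# 34 cortical parcels per hemisphere (Desikan-Killiany), FreeSurfer spelling.
CORTICAL_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

HEMISPHERES: tuple[str, ...] = ("left", "right")

# Metric suffixes for cortical parcels.
CORTICAL_METRICS: tuple[str, ...] = ("area", "thickness", "curvature", "folding_index")

# Default 14 subcortical grey-matter nuclei (bilateral).  The set is a
# convention, configurable by callers that ingest other segmentations.
SUBCORTICAL_STRUCTURES: tuple[str, ...] = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)

# FreeSurfer aseg StructName -> (hemi, structure) mapping for the default set.
ASEG_NAME_MAP: dict[str, tuple[str, str]] = {
    "Left-Thalamus-Proper": ("left", "thalamus"),
    "Left-Thalamus": ("left", "thalamus"),
    "Left-Caudate": ("left", "caudate"),
    "Left-Putamen": ("left", "putamen"),
    "Left-Pallidum": ("left", "pallidum"),
    "Left-Hippocampus": ("left", "hippocampus"),
    "Left-Amygdala": ("left", "amygdala"),
    "Left-Accumbens-area": ("left", "accumbens"),
    "Right-Thalamus-Proper": ("right", "thalamus"),
    "Right-Thalamus": ("right", "thalamus"),
    "Right-Caudate": ("right", "caudate"),
    "Right-Putamen": ("right", "putamen"),
    "Right-Pallidum": ("right", "pallidum"),
    "Right-Hippocampus": ("right", "hippocampus"),
    "Right-Amygdala": ("right", "amygdala"),
    "Right-Accumbens-area": ("right", "accumbens"),
}


def feature_name(hemi: str, region: str, metric: str) -> str:
    """Canonical column name for one regional measurement."""
    return f"{hemi}_{region}_{metric}"


def cortical_region_names() -> list[str]:
    """The 68 hemisphere-qualified cortical region names, fixed order."""
    return [f"{h}_{r}" for h in HEMISPHERES for r in CORTICAL_REGIONS]


def cortical_feature_names() -> list[str]:
    """The 272 cortical feature columns (68 regions x 4 metrics)."""
    return [
        feature_name(h, r, m)
        for h in HEMISPHERES
        for r in CORTICAL_REGIONS
        for m in CORTICAL_METRICS
    ]


def subcortical_feature_names(
    structures: tuple[str, ...] = SUBCORTICAL_STRUCTURES,
) -> list[str]:
    """The 14 subcortical volume columns (7 bilateral nuclei)."""
    return [feature_name(h, s, "volume") for h in HEMISPHERES for s in structures]


def all_feature_names() -> list[str]:
    """All 286 feature columns in canonical order."""
    return cortical_feature_names() + subcortical_feature_names()


def parse_feature_name(name: str) -> tuple[str, str, str]:
    """Split a canonical feature name into ``(hemi, region, metric)``.

    The region itself never contains an underscore, but metrics may
    (``folding_index``), so split on the first and second separators.
    """
    parts = name.split("_", 2)
    if len(parts) != 3 or parts[0] not in HEMISPHERES:
        raise ValueError(f"not a canonical feature name: {name!r}")
    hemi, region, metric = parts
    if metric not in CORTICAL_METRICS + ("volume",):
        raise ValueError(f"unknown metric in feature name: {name!r}")
    return hemi, region, metric


def region_of_feature(name: str) -> str:
    """Hemisphere-qualified region a feature column belongs to."""
    hemi, region, _ = parse_feature_name(name)
    return f"{hemi}_{region}"
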