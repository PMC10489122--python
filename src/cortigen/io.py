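"""Readers and writers for cohort feature tables and FreeSurfer stats files.

The package's on-disk interchange format is a single tab-separated file:
one row per participant, the cohort columns (id, genotype flags,
covariates) first, then the 286 canonical feature columns.  A YAML
sidecar records the generation parameters when the table was simulated.

Real data enters through the FreeSurfer regional-statistics dialect:
``?h.aparc.stats`` (one per hemisphere) and ``aseg.stats``, plain-text
tables whose header lines start with ``#`` and whose column names are
announced on a ``# ColHeaders`` line.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .atlas import (
    ASEG_NAME_MAP,
    CORTICAL_REGIONS,
    all_feature_names,
    feature_name,
    parse_feature_name,
)
from .simulate import COHORT_COLUMNS, EffectConfig

_POSITIVE_METRICS = {"area", "thickness", "volume"}


def write_feature_table(
    cohort: pd.DataFrame,
    features: pd.DataFrame,
    path: str | Path,
    config: EffectConfig | None = None,
) -> Path:
    """Write cohort + features as one TSV; optionally a YAML sidecar.

    The sidecar (``<path>.yaml``) records every generation parameter of
    ``config`` including the seed, so a simulated table is reproducible
    from its own metadata.
    """
    path = Path(path)
    table = pd.concat([cohort.reset_index(drop=True), features.reset_index(drop=True)], axis=1)
    table.to_csv(path, sep="\t", index=False)
    if config is not None:
        meta = dataclasses.asdict(config)
        meta["interaction_regions"] = list(meta["interaction_regions"])
        meta["covariate_slopes"] = {k: list(v) for k, v in meta["covariate_slopes"].items()}
        with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_feature_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a feature table written by :func:`write_feature_table`.

    Returns ``(cohort, features)``.  Validation failures (missing
    mandatory columns, duplicate participant ids, non-numeric cells,
    non-binary genotype flags, non-positive areas/thicknesses/volumes)
    raise ``ValueError`` naming the offending row and column.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"participant_id": str})

    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    ids = table["participant_id"]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate participant id(s) {sorted(set(dup))}")

    feature_cols = [c for c in table.columns if c not in COHORT_COLUMNS]
    for col in list(COHORT_COLUMNS[1:]) + feature_cols:
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[numeric.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or missing value in column {col!r}, row {bad[0]} "
                f"(participant {ids.iloc[bad[0]]!r})"
            )
        table[col] = numeric

    for col in ("apoe_pos", "mapt_pos", "sex"):
        if not table[col].isin([0, 1]).all():
            bad = table.index[~table[col].isin([0, 1])][0]
            raise ValueError(f"{path}: column {col!r} must be 0/1, row {bad} is {table[col].iloc[bad]}")

    for col in feature_cols:
        _, _, metric = parse_feature_name(col)  # rejects unknown columns
        if metric in _POSITIVE_METRICS and (table[col] <= 0).any():
            bad = table.index[table[col] <= 0][0]
            raise ValueError(
                f"{path}: non-positive {metric} in column {col!r}, row {bad} "
                f"(participant {ids.iloc[bad]!r}, value {table[col].iloc[bad]})"
            )

    cohort = table[list(COHORT_COLUMNS)].copy()
    cohort[["apoe_pos", "mapt_pos", "sex", "education"]] = cohort[
        ["apoe_pos", "mapt_pos", "sex", "education"]
    ].astype(int)
    features = table[feature_cols].copy()
    return cohort, features


def _read_stats_table(path: str | Path) -> pd.DataFrame:
    """Parse one FreeSurfer stats file into a DataFrame.

    Header lines begin with ``#``; the ``# ColHeaders`` line names the
    whitespace-delimited data columns that follow.
    """
    path = Path(path)
    colheaders: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("ColHeaders"):
                    colheaders = body.split()[1:]
                continue
            rows.append(line.split())
    if colheaders is None:
        raise ValueError(f"{path}: no '# ColHeaders' line found")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    for i, row in enumerate(rows):
        if len(row) != len(colheaders):
            raise ValueError(
                f"{path}: truncated or malformed data row {i} "
                f"({len(row)} fields, expected {len(colheaders)})"
            )
    df = pd.DataFrame(rows, columns=colheaders)
    for col in df.columns:
        if col != "StructName":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_freesurfer_stats(
    aparc_lh: str | Path,
    aparc_rh: str | Path,
    aseg: str | Path,
    *,
    require_complete: bool = True,
) -> pd.Series:
    """Assemble one participant's 286-feature vector from stats files.

    Reads ``SurfArea``, ``ThickAvg``, ``MeanCurv`` and ``FoldInd`` per
    cortical parcel from the two aparc files, and ``Volume_mm3`` for the
    14 default subcortical nuclei from the aseg file.  Unknown cortical
    parcel names are rejected; with ``require_complete`` every expected
    region and nucleus must be present.
    """
    values: dict[str, float] = {}
    known = set(CORTICAL_REGIONS)
    for hemi, path in (("left", aparc_lh), ("right", aparc_rh)):
        df = _read_stats_table(path)
        needed = ["StructName", "SurfArea", "ThickAvg", "MeanCurv", "FoldInd"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
        for _, row in df.iterrows():
            region = str(row["StructName"])
            if region not in known:
                raise ValueError(f"{path}: unknown cortical parcel {region!r}")
            values[feature_name(hemi, region, "area")] = float(row["SurfArea"])
            values[feature_name(hemi, region, "thickness")] = float(row["ThickAvg"])
            values[feature_name(hemi, region, "curvature")] = float(row["MeanCurv"])
            values[feature_name(hemi, region, "folding_index")] = float(row["FoldInd"])

    df = _read_stats_table(aseg)
    for col in ("StructName", "Volume_mm3"):
        if col not in df.columns:
            raise ValueError(f"{aseg}: missing column {col!r}")
    for _, row in df.iterrows():
        struct = str(row["StructName"])
        if struct in ASEG_NAME_MAP:
            hemi, nucleus = ASEG_NAME_MAP[struct]
            values[feature_name(hemi, nucleus, "volume")] = float(row["Volume_mm3"])

    if require_complete:
        expected = all_feature_names()
        absent = [n for n in expected if n not in values]
        if absent:
            raise ValueError(
                f"incomplete stats files: {len(absent)} feature(s) missing, "
                f"first {absent[:5]}"
            )
        return pd.Series([values[n] for n in expected], index=expected, dtype=float)
    return pd.Series(values, dtype=float)
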