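"""Readers for FreeSurfer per-subject regional statistics tables.

FreeSurfer writes, per subject, a subcortical segmentation table
(``aseg.stats``) and one cortical parcellation table per hemisphere
(``lh.aparc.stats`` / ``rh.aparc.stats``). All are plain text: ``#``
comment headers, a ``# ColHeaders`` line naming the columns, then
whitespace-separated rows. This module parses those tables and assembles
a subject-by-feature :class:`~metaroi.cohort.FeatureTable` of bilateral
regional quantities:

* volume  = left + right (GrayVol for cortex, Volume_mm3 for segmentations)
* surface = left + right SurfArea
* thickness = surface-area-weighted mean of the hemispheric ThickAvg values
* total-ventricle = sum of the lateral, inferior-lateral, 3rd and 4th
  ventricle segmentations (configurable)

A fixture writer is included so tests can plant known values in
syntactically valid stats files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import FeatureKey, FeatureTable

__all__ = [
    "SegmentationRecord",
    "ParcellationRecord",
    "read_aseg_stats",
    "read_aparc_stats",
    "assemble_features",
    "write_synthetic_aseg_stats",
    "write_synthetic_aparc_stats",
]

logger = logging.getLogger(__name__)

#: cortical regions used in the default feature set, FreeSurfer StructName
#: -> package region name
DEFAULT_CORTICAL_MAP = {
    "entorhinal": "entorhinal",
    "fusiform": "fusiform",
    "inferiortemporal": "inferior-temporal",
    "middletemporal": "middle-temporal",
    "temporalpole": "temporal-pole",
    "precuneus": "precuneus",
    "parahippocampal": "para-hippocampal",
}

#: subcortical structures: package region -> (left StructName, right StructName)
DEFAULT_SUBCORTICAL_MAP = {
    "hippocampus": ("Left-Hippocampus", "Right-Hippocampus"),
    "amygdala": ("Left-Amygdala", "Right-Amygdala"),
    "inferior-lateral-ventricle": ("Left-Inf-Lat-Vent", "Right-Inf-Lat-Vent"),
}

DEFAULT_VENTRICLE_STRUCTURES = (
    "Left-Lateral-Ventricle",
    "Right-Lateral-Ventricle",
    "Left-Inf-Lat-Vent",
    "Right-Inf-Lat-Vent",
    "3rd-Ventricle",
    "4th-Ventricle",
)


@dataclass(frozen=True)
class SegmentationRecord:
    structure: str
    volume_mm3: float


@dataclass(frozen=True)
class ParcellationRecord:
    hemisphere: str
    region: str
    surface_mm2: float
    gray_volume_mm3: float
    thickness_mm: float


def _parse_stats(path: str | Path) -> tuple[list[str], list[list[str]], dict[str, str]]:
    """Split a FreeSurfer stats file into column names, data rows and
    header metadata (``# key value`` lines)."""
    path = Path(path)
    columns: list[str] | None = None
    rows: list[list[str]] = []
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("ColHeaders"):
                    columns = body.split()[1:]
                else:
                    parts = body.split(None, 1)
                    if len(parts) == 2:
                        meta[parts[0]] = parts[1]
                continue
            fields = line.split()
            if columns is not None and len(fields) < len(columns):
                raise ValueError(
                    f"{path}:{lineno}: truncated row ({len(fields)} fields, "
                    f"expected {len(columns)})"
                )
            rows.append(fields)
    if columns is None:
        raise ValueError(f"{path}: no '# ColHeaders' line found")
    return columns, rows, meta


def read_aseg_stats(path: str | Path) -> list[SegmentationRecord]:
    """Parse a subcortical segmentation table into structure volumes."""
    columns, rows, _ = _parse_stats(path)
    try:
        i_name = columns.index("StructName")
        i_vol = columns.index("Volume_mm3")
    except ValueError as exc:
        raise ValueError(f"{path}: missing required column: {exc}") from None
    return [SegmentationRecord(r[i_name], float(r[i_vol])) for r in rows]


def read_aparc_stats(path: str | Path, hemisphere: str) -> list[ParcellationRecord]:
    """Parse one hemisphere's cortical parcellation table.

    If the file's own ``# hemi`` marker disagrees with the ``hemisphere``
    argument a warning is logged and parsing proceeds with the argument.
    """
    if hemisphere not in ("lh", "rh"):
        raise ValueError(f"hemisphere must be 'lh' or 'rh', got {hemisphere!r}")
    columns, rows, meta = _parse_stats(path)
    marked = meta.get("hemi")
    if marked and marked != hemisphere:
        logger.warning(
            "%s: file marked hemi=%s but read as %s", path, marked, hemisphere
        )
    try:
        idx = {c: columns.index(c) for c in ("StructName", "SurfArea", "GrayVol", "ThickAvg")}
    except ValueError as exc:
        raise ValueError(f"{path}: missing required column: {exc}") from None
    return [
        ParcellationRecord(
            hemisphere=hemisphere,
            region=r[idx["StructName"]],
            surface_mm2=float(r[idx["SurfArea"]]),
            gray_volume_mm3=float(r[idx["GrayVol"]]),
            thickness_mm=float(r[idx["ThickAvg"]]),
        )
        for r in rows
    ]


def assemble_features(
    stats_root: str | Path,
    manifest: Mapping[str, str],
    *,
    cortical_map: Mapping[str, str] = DEFAULT_CORTICAL_MAP,
    subcortical_map: Mapping[str, tuple[str, str]] = DEFAULT_SUBCORTICAL_MAP,
    ventricle_structures: Sequence[str] = DEFAULT_VENTRICLE_STRUCTURES,
    thickness_weighting: str = "surface",
) -> FeatureTable:
    """Build a bilateral feature table from per-subject stats directories.

    ``stats_root/<subject_id>/`` must contain ``aseg.stats``,
    ``lh.aparc.stats`` and ``rh.aparc.stats``; ``manifest`` maps subject id
    to diagnostic group. Subjects with a missing or unparsable file are
    excluded with a logged reason. ``thickness_weighting`` is ``"surface"``
    (area-weighted hemispheric mean, the default) or ``"simple"``.
    """
    if thickness_weighting not in ("surface", "simple"):
        raise ValueError("thickness_weighting must be 'surface' or 'simple'")
    stats_root = Path(stats_root)
    rows: dict[str, dict[str, float]] = {}
    groups: dict[str, str] = {}
    for subject_id, group in manifest.items():
        subj_dir = stats_root / subject_id
        try:
            segs = {s.structure: s.volume_mm3 for s in read_aseg_stats(subj_dir / "aseg.stats")}
            parc = {
                hemi: {p.region: p for p in read_aparc_stats(subj_dir / f"{hemi}.aparc.stats", hemi)}
                for hemi in ("lh", "rh")
            }
        except (OSError, ValueError) as exc:
            logger.warning("excluding subject %s: %s", subject_id, exc)
            continue
        values: dict[str, float] = {}
        try:
            for fs_name, region in cortical_map.items():
                left, right = parc["lh"][fs_name], parc["rh"][fs_name]
                area = left.surface_mm2 + right.surface_mm2
                values[FeatureKey(region, "volume").column] = (
                    left.gray_volume_mm3 + right.gray_volume_mm3
                )
                values[FeatureKey(region, "surface").column] = area
                if thickness_weighting == "surface" and area > 0:
                    thick = (
                        left.thickness_mm * left.surface_mm2
                        + right.thickness_mm * right.surface_mm2
                    ) / area
                else:
                    thick = 0.5 * (left.thickness_mm + right.thickness_mm)
                values[FeatureKey(region, "thickness").column] = thick
            for region, (l_name, r_name) in subcortical_map.items():
                values[FeatureKey(region, "volume").column] = segs[l_name] + segs[r_name]
            values[FeatureKey("total-ventricle", "volume").column] = sum(
                segs[s] for s in ventricle_structures
            )
        except KeyError as exc:
            logger.warning("excluding subject %s: missing structure %s", subject_id, exc)
            continue
        rows[subject_id] = values
        groups[subject_id] = group
    if not rows:
        raise ValueError("no subject could be assembled from the given manifest")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.insert(0, "group", pd.Series(groups))
    df.index.name = "subject_id"
    return FeatureTable(df)


def write_synthetic_aseg_stats(
    path: str | Path, volumes: Mapping[str, float]
) -> None:
    """Write a synthetic subcortical stats file with planted volumes.

    Produces the standard layout (comment header, ColHeaders line,
    whitespace rows) for testing; the contents are synthetic, not
    FreeSurfer output.
    """
    lines = [
        "# Title Segmentation Statistics (synthetic fixture)",
        "# ColHeaders Index SegId NVoxels Volume_mm3 StructName normMean",
    ]
    for i, (name, vol) in enumerate(volumes.items(), start=1):
        lines.append(f" {i} {i + 10} {int(vol)} {vol:.1f} {name} 0.0")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_synthetic_aparc_stats(
    path: str | Path,
    hemisphere: str,
    regions: Mapping[str, tuple[float, float, float]],
) -> None:
    """Write a synthetic parcellation stats file.

    ``regions`` maps StructName -> (SurfArea mm^2, GrayVol mm^3,
    ThickAvg mm). Synthetic fixture layout, not FreeSurfer output.
    """
    lines = [
        "# Title Cortical Parcellation Statistics (synthetic fixture)",
        f"# hemi {hemisphere}",
        "# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg ThickStd",
    ]
    for name, (area, vol, thick) in regions.items():
        lines.append(f"{name} {int(area)} {area:.1f} {vol:.1f} {thick:.3f} 0.100")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
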