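"""Subject-level feature tables and group-contrast detectability reports.

A :class:`FeatureTable` holds one row per subject with a diagnostic group
label (NC / MCI / AD) and one column per regional morphometry feature,
named ``region.measure`` (e.g. ``entorhinal.thickness``). From it the
module derives per-group summary statistics and the full detectability
report — detectability index, binormal AUC, symmetric percent change and
ideal-observer cut-off — for any ordered sequence of group contrasts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sdt import (
    GaussianPair,
    GroupStats,
    auc_from_d,
    detectability_index,
    ideal_observer_cutoff,
    percent_change,
)

__all__ = [
    "GROUP_LABELS",
    "MEASURES",
    "FeatureKey",
    "FeatureTable",
    "RoiSummary",
    "summarize",
    "detectability_table",
    "read_feature_table",
    "write_feature_table",
]

logger = logging.getLogger(__name__)

GROUP_LABELS = ("NC", "MCI", "AD")
MEASURES = ("thickness", "volume", "surface")


@dataclass(frozen=True, order=True)
class FeatureKey:
    """A (region, measure) pair identifying one morphometry feature."""

    region: str
    measure: str

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(
                f"measure must be one of {MEASURES}, got {self.measure!r}"
            )

    @property
    def column(self) -> str:
        return f"{self.region}.{self.measure}"

    @classmethod
    def from_column(cls, column: str) -> "FeatureKey":
        region, sep, measure = column.rpartition(".")
        if not sep or not region:
            raise ValueError(
                f"feature column {column!r} is not of the form region.measure"
            )
        return cls(region, measure)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.column


@dataclass
class FeatureTable:
    """One row per subject: diagnostic group plus feature values.

    ``data`` is indexed by subject id with a ``group`` column followed by
    one numeric column per feature. All feature columns must parse as
    ``region.measure`` and group labels must be NC, MCI or AD.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.data.columns:
            raise ValueError("feature table needs a 'group' column")
        bad = set(self.data["group"]) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate subject ids: {list(dupes)[:5]}")
        for col in self.feature_columns:
            FeatureKey.from_column(col)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != "group"]

    @property
    def features(self) -> list[FeatureKey]:
        return [FeatureKey.from_column(c) for c in self.feature_columns]

    @property
    def groups(self) -> list[str]:
        present = set(self.data["group"])
        return [g for g in GROUP_LABELS if g in present]

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, groups: Iterable[str]) -> "FeatureTable":
        """Rows belonging to the given groups, in original order."""
        groups = list(groups)
        return FeatureTable(self.data[self.data["group"].isin(groups)].copy())

    def xy(self, features: Sequence[FeatureKey], signal_group: str):
        """Design matrix and binary labels (1 = signal group)."""
        cols = [f.column for f in features]
        x = self.data[cols].to_numpy(dtype=float)
        y = (self.data["group"] == signal_group).to_numpy(dtype=int)
        return x, y


@dataclass(frozen=True)
class RoiSummary:
    """Per-group mean/SD/n of one feature (one row of a summary report)."""

    feature: FeatureKey
    stats: Mapping[str, GroupStats]


def summarize(table: FeatureTable) -> list[RoiSummary]:
    """Per-feature, per-group mean and sample SD (n-1 denominator).

    Subjects with a missing value for a feature are dropped from that
    feature's summary only, with a logged count. A group with fewer than
    two usable subjects for a feature is an error.
    """
    out: list[RoiSummary] = []
    for col in table.feature_columns:
        key = FeatureKey.from_column(col)
        stats: dict[str, GroupStats] = {}
        for group, values in table.data.groupby("group", observed=True)[col]:
            clean = values.dropna()
            dropped = len(values) - len(clean)
            if dropped:
                logger.warning(
                    "dropped %d subject(s) with missing %s in group %s",
                    dropped, col, group,
                )
            if len(clean) < 2:
                raise ValueError(
                    f"group {group} has {len(clean)} usable subject(s) for "
                    f"{col}; need at least 2"
                )
            stats[str(group)] = GroupStats(
                mean=float(clean.mean()), sd=float(clean.std(ddof=1)), n=len(clean)
            )
        out.append(RoiSummary(feature=key, stats=stats))
    return out


def detectability_table(
    summaries: Sequence[RoiSummary],
    pairs: Sequence[tuple[str, str]] = (("NC", "AD"), ("MCI", "AD"), ("NC", "MCI")),
) -> pd.DataFrame:
    """Detectability report over features x ordered group contrasts.

    Each ``(reference, signal)`` pair (e.g. ``("NC", "AD")``) yields the
    signed detectability index, the binormal AUC of its magnitude, the
    symmetric percent change from reference to signal, and the
    ideal-observer cut-off (NaN when the class models are identical).
    Rows are sortable by AUC descending per pair.
    """
    rows = []
    for summ in summaries:
        for ref_label, sig_label in pairs:
            for label in (ref_label, sig_label):
                if label not in summ.stats:
                    raise KeyError(
                        f"feature {summ.feature.column} has no stats for "
                        f"group {label}"
                    )
            ref, sig = summ.stats[ref_label], summ.stats[sig_label]
            if math.isclose(ref.mean, sig.mean) and math.isclose(ref.sd, sig.sd):
                d_a, auc, pct, cut = 0.0, 0.5, 0.0, float("nan")
            else:
                d_a = detectability_index(signal=sig, background=ref)
                auc = auc_from_d(abs(d_a))
                pct = percent_change(reference=ref, comparison=sig)
                try:
                    cut = ideal_observer_cutoff(GaussianPair(signal=sig, background=ref))
                except ValueError:
                    cut = float("nan")
            rows.append(
                {
                    "region": summ.feature.region,
                    "measure": summ.feature.measure,
                    "pair": f"{ref_label}_{sig_label}",
                    "d_a": d_a,
                    "auc": auc,
                    "percent_change": pct,
                    "cutoff": cut,
                }
            )
    return pd.DataFrame(rows)


def read_feature_table(
    path: str | Path,
    *,
    sep: str | None = None,
    group_aliases: Mapping[str, str] | None = None,
) -> FeatureTable:
    """Read a delimiter-separated subject-level feature table.

    The header must name ``subject_id``, ``group`` and then feature columns
    as ``region.measure``. ``sep=None`` sniffs comma vs tab from the header
    line. ``group_aliases`` maps nonstandard labels onto the NC/MCI/AD
    vocabulary (e.g. ``{"CN": "NC"}``); unmapped unknown labels are an
    error naming the offending lines.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if sep is None:
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str, "group": str})
    if df.columns[0] != "subject_id" or "group" not in df.columns[:2]:
        raise ValueError(
            f"{path}: header must start with subject_id, group; got "
            f"{list(df.columns[:2])}"
        )
    if group_aliases:
        df["group"] = df["group"].replace(dict(group_aliases))
    unknown = ~df["group"].isin(GROUP_LABELS)
    if unknown.any():
        lines = (df.index[unknown] + 2).tolist()  # +2: header + 1-based
        raise ValueError(
            f"{path}: unknown group label(s) {sorted(set(df['group'][unknown]))} "
            f"on line(s) {lines[:10]}"
        )
    if df["subject_id"].duplicated().any():
        dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate subject_id(s) {dupes[:5]}")
    feature_cols = [c for c in df.columns if c not in ("subject_id", "group")]
    for col in feature_cols:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][:1]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value in column {col} (line {line})")
    return FeatureTable(df.set_index("subject_id"))


def write_feature_table(table: FeatureTable, path: str | Path, *, sep: str = ",") -> None:
    """Write a feature table; round-trips losslessly to 12+ significant digits."""
    df = table.data.reset_index(names="subject_id")
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")
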