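"""Segment aggregation, reference normalization and outcome labeling.

Each index map is reduced per segment to {min, max, mean} (area-weighted
means for surface indices, volume-weighted for lumen indices), lesion
segments are normalized statistic-by-statistic to the proximal healthy
reference segment (min/min, max/max, mean/mean), and lesions are labeled
progression / stable / regression from the serial change in diameter
stenosis: progression at ΔDS% >= 5, regression at ΔDS% <= -5, stable in
between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import REFERENCE_ID, SegmentDefinition
from .indices import IndexMaps

__all__ = [
    "SegmentSummary",
    "NormalizedSummary",
    "aggregate_segment",
    "normalize_to_reference",
    "label_outcome",
    "plaque_arithmetic",
    "build_cohort_table",
]

_STAT_PREFIX = {"mean": "Ave", "max": "Max", "min": "Min"}

#: map internal index field names to the cohort-table suffixes
INDEX_COLUMN_NAMES = {
    "tawss": "TAWSS",
    "osi": "OSI",
    "rrt": "RRT",
    "wssg": "WSSG",
    "gon": "GON",
    "vorticity_ta": "Vorticity",
    "helicity_ta": "Helicity",
}


@dataclass
class SegmentSummary:
    """{min, max, mean} of every index over one segment."""

    segment_id: int
    stats: dict  # index name -> {"min": x, "max": x, "mean": x}
    counts: dict  # index name -> members used
    flagged: dict  # index name -> members excluded as non-finite
    empty: bool = False


@dataclass
class NormalizedSummary:
    """Lesion statistics divided by the matching reference statistics."""

    segment_id: int
    values: dict  # index name -> {"min": ratio, "max": ratio, "mean": ratio}
    flagged: list = field(default_factory=list)  # (index, stat) with zero denominators


def _weighted_stats(values: np.ndarray, weights: np.ndarray):
    ok = np.isfinite(values)
    v, w = values[ok], weights[ok]
    n_flag = int(len(values) - ok.sum())
    if len(v) == 0:
        return None, 0, n_flag
    mean = float(np.average(v, weights=w)) if w.sum() > 0 else float(v.mean())
    return (
        {"min": float(v.min()), "max": float(v.max()), "mean": mean},
        int(len(v)),
        n_flag,
    )


def aggregate_segment(
    maps: IndexMaps,
    surface_assignment: np.ndarray,
    segdef: SegmentDefinition,
    surface_weights: np.ndarray | None = None,
    volume_assignment: np.ndarray | None = None,
    volume_weights: np.ndarray | None = None,
) -> list[SegmentSummary]:
    """Per-segment {min, max, mean} over unflagged vertices/points.

    Segment ids run 0 (reference) .. K (most distal lesion sub-segment).
    A segment with no unflagged members for an index carries ``None`` for
    that index; a segment with no members at all is marked ``empty``.
    """
    seg_ids = [REFERENCE_ID] + list(range(1, segdef.n_segments + 1))
    if surface_weights is None:
        surface_weights = np.ones(len(surface_assignment))
    out = []
    for sid in seg_ids:
        s_mask = surface_assignment == sid
        stats: dict = {}
        counts: dict = {}
        flagged: dict = {}
        any_members = bool(s_mask.any())
        for name, arr in maps.surface.items():
            st, n, nf = _weighted_stats(arr[s_mask], surface_weights[s_mask])
            stats[name], counts[name], flagged[name] = st, n, nf
        if maps.volume and volume_assignment is not None:
            v_mask = volume_assignment == sid
            any_members = any_members or bool(v_mask.any())
            vw = (
                volume_weights[v_mask]
                if volume_weights is not None
                else np.ones(int(v_mask.sum()))
            )
            for name, arr in maps.volume.items():
                st, n, nf = _weighted_stats(arr[v_mask], vw)
                stats[name], counts[name], flagged[name] = st, n, nf
        out.append(
            SegmentSummary(
                segment_id=sid,
                stats=stats,
                counts=counts,
                flagged=flagged,
                empty=not any_members,
            )
        )
    return out


def normalize_to_reference(
    lesion: SegmentSummary, reference: SegmentSummary
) -> NormalizedSummary:
    """Statistic-matched normalization: lesion min/ref min, max/max, mean/mean.

    Zero (or missing) reference statistics flag the ratio as NaN and record
    the (index, statistic) pair instead of propagating 0/0.
    """
    if set(lesion.stats) != set(reference.stats):
        raise ValidationError("lesion and reference must share the same index panel")
    values: dict = {}
    flagged: list = []
    for name, les in lesion.stats.items():
        ref = reference.stats[name]
        values[name] = {}
        for stat in ("min", "max", "mean"):
            if les is None or ref is None or ref[stat] == 0 or not np.isfinite(ref[stat]):
                values[name][stat] = np.nan
                flagged.append((name, stat))
            elif not np.isfinite(les[stat]):
                values[name][stat] = np.nan
                flagged.append((name, stat))
            else:
                values[name][stat] = les[stat] / ref[stat]
    return NormalizedSummary(segment_id=lesion.segment_id, values=values, flagged=flagged)


def label_outcome(delta_ds_percent: float) -> str:
    """Serial-change label: >= +5 progression, <= -5 regression, else stable."""
    d = float(delta_ds_percent)
    if not np.isfinite(d):
        raise ValidationError("ΔDS% must be finite")
    if d >= 5.0:
        return "progression"
    if d <= -5.0:
        return "regression"
    return "stable"


def plaque_arithmetic(
    lipid: float,
    fibrous: float,
    calcified: float,
    proximal_area: float | None = None,
    mla: float | None = None,
) -> dict:
    """Plaque composition sums and the area stenosis degree.

    total = lipid + fibrous + calcified; non-calcified = lipid + fibrous;
    stenosis degree = (proximal area - MLA) / proximal area x 100.
    """
    if min(lipid, fibrous, calcified) < 0:
        raise ValidationError("plaque volumes must be nonnegative")
    out = {
        "total": lipid + fibrous + calcified,
        "non_calcified": lipid + fibrous,
    }
    if proximal_area is not None and mla is not None:
        if proximal_area <= 0:
            raise ValidationError("proximal area must be positive")
        out["stenosis_degree"] = (proximal_area - mla) / proximal_area * 100.0
    return out


def build_cohort_table(records: list[dict]) -> pd.DataFrame:
    """One row per lesion sub-segment, columns named N.Ave./N.Max./N.Min.<index>.

    Each record needs keys ``patient_id``, ``vessel_id``, ``segment_id``,
    ``normalized`` (a :class:`NormalizedSummary`), ``delta_DS_percent`` and
    optional extra scalar columns.  Duplicate (vessel, segment) keys raise.
    """
    schema_cols = ["patient_id", "vessel_id", "segment_id"]
    rows = []
    seen = set()
    for rec in records:
        key = (rec["vessel_id"], rec["segment_id"])
        if key in seen:
            raise ValidationError(f"duplicate (vessel, segment) key: {key}")
        seen.add(key)
        row = {k: rec[k] for k in schema_cols}
        norm: NormalizedSummary = rec["normalized"]
        for name, stats in norm.values.items():
            suffix = INDEX_COLUMN_NAMES.get(name, name)
            for stat, val in stats.items():
                row[f"N.{_STAT_PREFIX[stat]}.{suffix}"] = val
        dds = rec["delta_DS_percent"]
        row["delta_DS_percent"] = dds
        row["label"] = rec.get("label", label_outcome(dds))
        for k, v in rec.items():
            if k not in row and k not in ("normalized",):
                row[k] = v
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=schema_cols + ["delta_DS_percent", "label"]
        )
    return pd.DataFrame(rows)
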