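"""Fixation-table I/O and area-of-interest (AOI) assignment.

Fixation tables are delimited text exported from an eye tracker, one row per
fixation with start/duration/end in milliseconds and a 2-D screen position in
pixels.  The stimulus frame uses the dominant eye-tracking convention: origin
at the top-left corner, x rightward, y downward.

The visual field is divided into five named regions — pavement area (PA),
central area (CA), top wall (TW), left wall (LW), right wall (RW) — and the
implicit complement, white space (WS).  Every screen point maps to exactly one
of those six labels; points on a shared boundary are resolved by a fixed
priority order (PA first by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import Point, Polygon

from .errors import ConfigError, GeometryError, ValidationError

logger = logging.getLogger(__name__)

#: The five named AOI labels, in default boundary-priority order.
AOI_LABELS: tuple[str, ...] = ("PA", "CA", "TW", "LW", "RW")

#: Label for the complement of the five regions.
WS = "WS"

#: All six area labels (five regions plus white space).
ALL_AREAS: tuple[str, ...] = AOI_LABELS + (WS,)

SCENARIOS: tuple[str, ...] = ("A", "B", "C")
ALIGNMENTS: tuple[str, ...] = ("straight", "left_curve", "right_curve")

#: Grouping key identifying one trial (one drive through one condition).
TRIAL_KEYS: list[str] = ["participant", "scenario", "alignment"]

#: Internal column names for a fixation table.
FIXATION_COLUMNS: list[str] = TRIAL_KEYS + [
    "start_ms",
    "duration_ms",
    "end_ms",
    "pos_x",
    "pos_y",
]

#: Default mapping from logical column -> column name in the delimited file.
DEFAULT_SCHEMA: dict[str, str] = {
    "participant": "participant",
    "scenario": "scenario",
    "alignment": "alignment",
    "start_ms": "fixation_start_ms",
    "duration_ms": "fixation_duration_ms",
    "end_ms": "fixation_end_ms",
    "pos_x": "position_x",
    "pos_y": "position_y",
}

_NUMERIC = ["start_ms", "duration_ms", "end_ms", "pos_x", "pos_y"]


def read_fixations(
    path: str | Path,
    schema: dict[str, str] | None = None,
    sep: str | None = None,
    drop_invalid: bool = False,
) -> pd.DataFrame:
    """Read and validate a fixation table.

    Parameters
    ----------
    path
        Delimited text file (comma or tab; auto-detected when *sep* is None).
    schema
        Mapping from logical column names (keys of :data:`DEFAULT_SCHEMA`) to
        the column names used in the file.  Missing keys fall back to the
        defaults.
    drop_invalid
        When True, rows violating row-level invariants are dropped and logged
        instead of raising :class:`ValidationError`.

    Returns
    -------
    DataFrame with columns :data:`FIXATION_COLUMNS`, sorted by
    (participant, scenario, alignment, start_ms).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"fixation file not found: {path}")
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(DEFAULT_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown schema keys: {sorted(unknown)}")
        colmap.update(schema)

    raw = pd.read_csv(path, sep=sep, engine="python")
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ConfigError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    df = raw.rename(columns={v: k for k, v in colmap.items()})[FIXATION_COLUMNS]
    if df.empty:
        logger.warning("%s: no fixation rows (header only)", path)
        return df.assign(**{c: pd.Series(dtype=float) for c in _NUMERIC})

    # header line is 1, first data row is 2
    lines = df.index.to_numpy() + 2

    bad_rows: list[str] = []
    num = df[_NUMERIC].apply(pd.to_numeric, errors="coerce")
    nonnum = num.isna().any(axis=1) & df[_NUMERIC].notna().any(axis=1)
    nonnum |= df[_NUMERIC].isna().any(axis=1)
    for ln in lines[nonnum.to_numpy()]:
        bad_rows.append(f"line {ln}: non-numeric or missing timing/position")
    df[_NUMERIC] = num

    ok = ~nonnum
    dur_bad = ok & ~(num["duration_ms"] > 0)
    for ln in lines[dur_bad.to_numpy()]:
        bad_rows.append(f"line {ln}: duration_ms must be > 0")
    end_bad = ok & (
        (num["start_ms"] + num["duration_ms"] - num["end_ms"]).abs() > 0.5
    )
    for ln in lines[end_bad.to_numpy()]:
        bad_rows.append(f"line {ln}: end_ms != start_ms + duration_ms")

    invalid = nonnum | dur_bad | end_bad
    if invalid.any():
        msg = "; ".join(bad_rows[:10])
        if not drop_invalid:
            raise ValidationError(f"{path}: {msg}")
        logger.warning("%s: dropping %d invalid row(s): %s", path, invalid.sum(), msg)
        df = df[~invalid]

    bad_labels = ~df["scenario"].astype(str).isin(SCENARIOS)
    bad_labels |= ~df["alignment"].astype(str).isin(ALIGNMENTS)
    if bad_labels.any():
        vals = df.loc[bad_labels, ["scenario", "alignment"]].drop_duplicates()
        raise ValidationError(
            f"{path}: unrecognised scenario/alignment labels: "
            f"{vals.to_dict('records')} (expected scenarios {SCENARIOS}, "
            f"alignments {ALIGNMENTS})"
        )

    df = df.sort_values(TRIAL_KEYS + ["start_ms"], kind="mergesort").reset_index(
        drop=True
    )
    _check_trial_ordering(df, str(path), drop_invalid)
    return df.reset_index(drop=True)


def _check_trial_ordering(df: pd.DataFrame, origin: str, drop_invalid: bool) -> None:
    """Within each trial fixations must be strictly ordered and non-overlapping."""
    for key, g in df.groupby(TRIAL_KEYS, sort=False, observed=True):
        starts = g["start_ms"].to_numpy()
        ends = g["end_ms"].to_numpy()
        if len(starts) < 2:
            continue
        if not np.all(np.diff(starts) > 0) or np.any(starts[1:] < ends[:-1] - 0.5):
            raise ValidationError(
                f"{origin}: overlapping or unordered fixations in trial "
                f"{dict(zip(TRIAL_KEYS, key))}"
            )


@dataclass(frozen=True)
class AOILayout:
    """Five labelled screen polygons plus the frame they live in.

    Any point not covered by a region is white space (WS); points on shared
    boundaries go to the first covering region in ``priority``.
    """

    frame_width: float
    frame_height: float
    regions: dict[str, Polygon]
    priority: tuple[str, ...] = field(default=AOI_LABELS)

    def __post_init__(self) -> None:
        missing = [lab for lab in AOI_LABELS if lab not in self.regions]
        if missing:
            raise ConfigError(f"AOI layout missing region(s): {', '.join(missing)}")
        extra = set(self.regions) - set(AOI_LABELS)
        if extra:
            raise ConfigError(f"AOI layout has unknown region(s): {sorted(extra)}")
        if sorted(self.priority) != sorted(AOI_LABELS):
            raise ConfigError(
                f"priority must be a permutation of {AOI_LABELS}, got {self.priority}"
            )
        for lab, poly in self.regions.items():
            if len(poly.exterior.coords) < 4:  # closed ring: 3 vertices + repeat
                raise GeometryError(f"region {lab}: polygon needs >= 3 vertices")
            if not poly.is_valid or poly.area <= 0:
                raise GeometryError(f"region {lab}: polygon is degenerate or self-intersecting")


def load_aoi_layout(path: str | Path) -> AOILayout:
    """Load an AOI layout from a YAML/JSON config.

    Expected structure::

        frame: {width: 1920, height: 1080}
        regions:
          PA: [[x1, y1], [x2, y2], ...]
          ...
        priority: [PA, CA, TW, LW, RW]   # optional
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"AOI layout file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "regions" not in cfg:
        raise ConfigError(f"{path}: layout must declare a 'regions' mapping")
    frame = cfg.get("frame", {})
    regions_cfg = cfg["regions"]
    missing = [lab for lab in AOI_LABELS if lab not in regions_cfg]
    if missing:
        raise ConfigError(f"{path}: missing region(s): {', '.join(missing)}")
    regions = {}
    for lab in AOI_LABELS:
        verts = regions_cfg[lab]
        if not isinstance(verts, list) or len(verts) < 3:
            raise GeometryError(
                f"{path}: region {lab} needs at least 3 vertices, got {len(verts)}"
            )
        regions[lab] = Polygon([(float(x), float(y)) for x, y in verts])
    priority = tuple(cfg.get("priority", AOI_LABELS))
    return AOILayout(
        frame_width=float(frame.get("width", 1920)),
        frame_height=float(frame.get("height", 1080)),
        regions=regions,
        priority=priority,
    )


def default_layout() -> AOILayout:
    """Synthetic tunnel-view layout on a 1920x1080 frame.

    A schematic forward view from the driver's seat: a top-wall band with the
    tunnel lamps, left/right wall bands carrying wall delineators, the central
    area around the vanishing point, and a wide pavement band at the bottom.
    The margins of the frame are white space.  This layout is an engineering
    default, not measured from any study.
    """
    rect = lambda x0, y0, x1, y1: Polygon(
        [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
    )
    return AOILayout(
        frame_width=1920,
        frame_height=1080,
        regions={
            "TW": rect(260, 60, 1660, 300),
            "LW": rect(260, 300, 660, 780),
            "CA": rect(660, 300, 1260, 780),
            "RW": rect(1260, 300, 1660, 780),
            "PA": rect(260, 780, 1660, 1020),
        },
    )


def assign_fixation(x: float, y: float, layout: AOILayout) -> str:
    """Map one screen point to its unique area label (total function)."""
    p = Point(float(x), float(y))
    for lab in layout.priority:
        if layout.regions[lab].covers(p):
            return lab
    return WS


def label_table(fixations: pd.DataFrame, layout: AOILayout) -> pd.DataFrame:
    """Assign every fixation an ``aoi`` label via :func:`assign_fixation`.

    Vectorised: each region is tested once against all points, in priority
    order, so boundary ties resolve identically to the scalar function.
    """
    out = fixations.copy()
    if out.empty:
        out["aoi"] = pd.Series(dtype=str)
        return out
    pts = shapely.points(
        np.column_stack([out["pos_x"].to_numpy(float), out["pos_y"].to_numpy(float)])
    )
    labels = np.full(len(out), WS, dtype=object)
    unassigned = np.ones(len(out), dtype=bool)
    for lab in layout.priority:
        hit = unassigned & shapely.covers(layout.regions[lab], pts)
        labels[hit] = lab
        unassigned &= ~hit
    out["aoi"] = labels
    return out


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a (labelled) fixation table as CSV."""
    table.to_csv(path, index=False)


def read_labeled_table(path: str | Path) -> pd.DataFrame:
    """Read back a labelled fixation table written by :func:`write_table`."""
    df = pd.read_csv(path)
    missing = [c for c in FIXATION_COLUMNS + ["aoi"] if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing column(s): {', '.join(missing)}")
    bad = ~df["aoi"].isin(ALL_AREAS)
    if bad.any():
        raise ValidationError(
            f"{path}: unknown aoi label(s): {sorted(df.loc[bad, 'aoi'].unique())}"
        )
    return df
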