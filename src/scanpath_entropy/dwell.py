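"""Per-area dwell time: total fixation duration T_s and proportion beta_s.

For each trial, T_s sums the fixation durations falling in area s over all
six areas (the five AOIs plus white space), T_total = sum_s T_s, and
beta_s = T_s / T_total.  Unlike the entropy stage, which drops white space,
the dwell stage keeps all six areas.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .io_aoi import ALL_AREAS, TRIAL_KEYS

logger = logging.getLogger(__name__)

#: Columns of the long-format dwell summary.
DWELL_COLUMNS = TRIAL_KEYS + ["area", "T_ms", "T_total_ms", "beta", "undefined"]


def area_durations(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trial, per-area total durations and proportions.

    Parameters
    ----------
    table
        Labelled fixation table (must carry an ``aoi`` column).

    Returns
    -------
    Long-format DataFrame with one row per trial x area (six areas per
    trial, areas never visited get ``T_ms = 0`` and ``beta = 0``).  A trial
    whose total duration is zero is flagged ``undefined = True`` with
    ``beta`` left as NA rather than silently propagating NaN.
    """
    if "aoi" not in table.columns:
        raise ValidationError("table has no 'aoi' column; run label_table first")
    rows = []
    for key, g in table.groupby(TRIAL_KEYS, sort=True, observed=True):
        per_area = g.groupby("aoi", observed=True)["duration_ms"].sum()
        total = int(g["duration_ms"].sum())
        undefined = total <= 0
        if undefined:
            logger.warning(
                "trial %s has zero total fixation time; proportions undefined",
                dict(zip(TRIAL_KEYS, key)),
            )
        for area in ALL_AREAS:
            t = int(per_area.get(area, 0))
            rows.append(
                dict(zip(TRIAL_KEYS, key))
                | {
                    "area": area,
                    "T_ms": t,
                    "T_total_ms": total,
                    "beta": (t / total) if not undefined else pd.NA,
                    "undefined": undefined,
                }
            )
    out = pd.DataFrame(rows, columns=DWELL_COLUMNS)
    return out


def dwell_report(
    summaries: pd.DataFrame,
    path: str | Path,
    figure_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Write the dwell-proportion table; optionally draw per-condition rings.

    The written table adds a ``percent`` column formatted like "55.0%"
    (proportions are reported to 3 decimals, percentages to 1).
    """
    out = summaries.copy()
    if out.empty:
        logger.warning("dwell_report: no summaries to report")
        out.to_csv(path, index=False)
        return out
    out["beta"] = out["beta"].astype(float).round(3)
    out["percent"] = out["beta"].map(
        lambda b: "" if pd.isna(b) else f"{100 * b:.1f}%"
    )
    out.to_csv(path, index=False)
    if figure_dir is not None:
        _ring_charts(out, Path(figure_dir))
    return out


def _ring_charts(summaries: pd.DataFrame, figure_dir: Path) -> None:
    """One donut chart of mean dwell proportions per scenario x alignment."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figure_dir.mkdir(parents=True, exist_ok=True)
    mean_beta = (
        summaries.dropna(subset=["beta"])
        .groupby(["scenario", "alignment", "area"], observed=True)["beta"]
        .mean()
    )
    for (scenario, alignment), sub in mean_beta.groupby(level=[0, 1]):
        vals = sub.droplevel([0, 1]).reindex(ALL_AREAS).fillna(0.0)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.pie(vals, labels=list(vals.index), wedgeprops=dict(width=0.4))
        ax.set_title(f"scenario {scenario}, {alignment}")
        fig.savefig(figure_dir / f"dwell_{scenario}_{alignment}.png", dpi=100)
        plt.close(fig)
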