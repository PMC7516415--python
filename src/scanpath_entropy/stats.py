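"""Group-level statistics over the per-trial entropy grid.

Two analyses mirror the study design (21 participants x 3 delineator
scenarios x 3 tunnel alignments):

* a two-way fixed-effects ANOVA (scenario, alignment, their interaction)
  with partial eta squared per effect.  All 189 observations enter one
  between-style model — participant is not a factor — giving residual
  df = N - (a*b) (180 for the full design).  The design must be balanced,
  which makes Type I/II/III sums of squares coincide;
* pairwise scenario "dominance": within one alignment, the percentage of
  participants whose entropy is strictly smaller under the first scenario
  of a pair (ties count as not smaller).
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path

import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ValidationError
from .io_aoi import ALIGNMENTS, SCENARIOS

logger = logging.getLogger(__name__)

VARIABLES = ("Ht_bits", "Hs_bits")

EFFECTS = ("scenario", "alignment", "interaction", "residual")


def _clean(table: pd.DataFrame, variable: str) -> pd.DataFrame:
    if variable not in table.columns:
        raise ValidationError(f"entropy table has no column {variable!r}")
    df = table.copy()
    if "excluded" in df.columns:
        n_excl = int(df["excluded"].sum())
        if n_excl:
            logger.warning("dropping %d excluded trial(s) from group stats", n_excl)
        df = df[~df["excluded"].astype(bool)]
    return df.dropna(subset=[variable])


def two_way_anova(table: pd.DataFrame, variable: str = "Ht_bits") -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction on one entropy variable.

    Returns a DataFrame indexed by effect (scenario, alignment, interaction,
    residual) with columns ``sum_sq``, ``df``, ``F``, ``p``, ``eta_p2``.

    Raises :class:`ValidationError` on an unbalanced/incomplete grid or when
    there are no residual degrees of freedom (e.g. a single participant).
    """
    df = _clean(table, variable)
    if df.empty:
        raise ValidationError("entropy table is empty after exclusions")
    cells = df.groupby(["scenario", "alignment"], observed=True)[variable].count()
    n_cells = len(list(itertools.product(df["scenario"].unique(), df["alignment"].unique())))
    if len(cells) < n_cells or cells.nunique() != 1:
        raise ValidationError(
            "unbalanced or incomplete design: per-cell counts "
            f"{cells.to_dict()}; the two-way ANOVA here requires equal cell counts"
        )
    if cells.iloc[0] < 2:
        raise ValidationError(
            "no residual degrees of freedom: need at least 2 observations per cell"
        )
    data = df.rename(columns={variable: "y"})
    model = smf.ols("y ~ C(scenario) * C(alignment)", data=data).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    if data["y"].nunique() == 1:
        # constant response: clear the numerical dust so effects are exactly null
        tab["sum_sq"] = 0.0
        tab["F"] = float("nan")
        tab["PR(>F)"] = float("nan")
    rename = {
        "C(scenario)": "scenario",
        "C(alignment)": "alignment",
        "C(scenario):C(alignment)": "interaction",
        "Residual": "residual",
    }
    tab = tab.rename(index=rename).reindex(list(EFFECTS))
    ss_resid = tab.loc["residual", "sum_sq"]
    denom = tab["sum_sq"] + ss_resid
    eta = (tab["sum_sq"] / denom.where(denom > 0)).fillna(0.0)
    eta[tab["sum_sq"] == 0] = 0.0  # no effect variance -> no effect size
    out = pd.DataFrame(
        {
            "sum_sq": tab["sum_sq"],
            "df": tab["df"].astype(int),
            "F": tab["F"],
            "p": tab["PR(>F)"],
            "eta_p2": eta,
        }
    )
    out.loc["residual", ["F", "p", "eta_p2"]] = [pd.NA, pd.NA, pd.NA]
    out.attrs["variable"] = variable
    return out


def dominance(
    table: pd.DataFrame,
    pair: tuple[str, str],
    alignment: str,
    variable: str = "Ht_bits",
) -> dict:
    """Share of participants strictly smaller under ``pair[0]`` than ``pair[1]``.

    Participants missing either arm are excluded and logged.  Returns a dict
    with the pair, alignment, variable, paired-participant count, the count
    strictly smaller, and the percentage rounded to the nearest integer.
    """
    first, second = pair
    df = _clean(table, variable)
    df = df[df["alignment"] == alignment]
    arms = {
        sc: df[df["scenario"] == sc].set_index("participant")[variable]
        for sc in (first, second)
    }
    common = arms[first].index.intersection(arms[second].index)
    missing = arms[first].index.symmetric_difference(arms[second].index)
    if len(missing):
        logger.warning(
            "dominance %s vs %s (%s): excluding unpaired participant(s) %s",
            first, second, alignment, sorted(missing),
        )
    a = arms[first].loc[common]
    b = arms[second].loc[common]
    n_smaller = int((a < b).sum())
    pct = round(100.0 * n_smaller / len(common)) if len(common) else 0
    return {
        "first": first,
        "second": second,
        "alignment": alignment,
        "variable": variable,
        "n_pairs": int(len(common)),
        "n_smaller": n_smaller,
        "percent_smaller": int(pct),
    }


def dominance_table(table: pd.DataFrame) -> pd.DataFrame:
    """All scenario pairs x alignments x variables (18 rows for the full design)."""
    pairs = [(a, b) for a, b in itertools.combinations(SCENARIOS, 2)]
    rows = [
        dominance(table, pair, alignment, variable)
        for variable in VARIABLES
        for alignment in ALIGNMENTS
        for pair in pairs
        if (table["alignment"] == alignment).any()
    ]
    return pd.DataFrame(rows)


def stats_report(
    anova_results: dict[str, pd.DataFrame],
    dominance_rows: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write delimited and human-readable reports; return the text report path.

    ``anova_results`` maps variable name -> the frame from
    :func:`two_way_anova`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines: list[str] = []
    if not anova_results and (dominance_rows is None or dominance_rows.empty):
        logger.warning("stats_report: nothing to report")
    for variable, tab in anova_results.items():
        tab.to_csv(out_dir / f"anova_{variable}.csv")
        lines.append(f"Two-way ANOVA on {variable}")
        lines.append(
            "  (between-style model over all trials; participant is not a factor)"
        )
        dfd = int(tab.loc["residual", "df"])
        for effect in ("scenario", "alignment", "interaction"):
            r = tab.loc[effect]
            lines.append(
                f"  {effect:<12} F({int(r['df'])},{dfd}) = {r['F']:.3f}, "
                f"p = {r['p']:.4g}, eta_p^2 = {r['eta_p2']:.3f}"
            )
        lines.append("")
    if dominance_rows is not None and not dominance_rows.empty:
        dominance_rows.to_csv(out_dir / "dominance.csv", index=False)
        lines.append("Pairwise scenario dominance (strictly smaller under first)")
        for _, r in dominance_rows.iterrows():
            lines.append(
                f"  {r['variable']:<8} {r['alignment']:<12} "
                f"{r['first']} < {r['second']}: {r['percent_smaller']}% "
                f"({r['n_smaller']}/{r['n_pairs']})"
            )
    report = out_dir / "stats_report.txt"
    report.write_text("\n".join(lines) + "\n")
    return report
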