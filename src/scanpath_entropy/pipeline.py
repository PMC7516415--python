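"""End-to-end orchestration: simulate, analyze, and the embedded reference trial.

Each run writes its artifacts plus a ``manifest.json`` recording the
configuration, package version, seed and input checksums, so any artifact
can be reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .dwell import area_durations, dwell_report
from .entropy import trial_entropy
from .errors import ConfigError
from .io_aoi import (
    AOILayout,
    default_layout,
    label_table,
    load_aoi_layout,
    read_fixations,
    write_table,
)
from .stats import VARIABLES, dominance_table, stats_report, two_way_anova
from .synthetic import CohortConfig, simulate_cohort
from . import worked_example

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Settings for one analysis run."""

    fixations_path: str | Path
    out_dir: str | Path
    layout_path: str | Path | None = None
    pi_mode: str = "empirical"
    drop_invalid: bool = False
    figures: bool = False
    seed: int = 0
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, mode: str, config: dict, inputs: list[Path]) -> None:
    manifest = {
        "mode": mode,
        "package_version": __version__,
        "config": config,
        "inputs": {str(p): _sha256(p) for p in inputs},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _setup_logging(out_dir: Path, level: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    root = logging.getLogger("scanpath_entropy")
    root.setLevel(level.upper())
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (out_dir / "run.log").resolve()
        for h in root.handlers
    ):
        fh = logging.FileHandler(out_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(fh)


def run_analyze(config: RunConfig) -> dict[str, Path]:
    """Full analysis: label -> dwell -> entropy grid -> group statistics.

    Returns a dict of artifact names to paths.  Stage failures raise with
    the stage named; trials too short for entropy estimation are flagged in
    the entropy table and dropped (with a log line) from group statistics.
    """
    out_dir = Path(config.out_dir)
    _setup_logging(out_dir, config.log_level)
    fix_path = Path(config.fixations_path)

    layout: AOILayout
    inputs = [fix_path]
    if config.layout_path is not None:
        layout_path = Path(config.layout_path)
        layout = load_aoi_layout(layout_path)
        inputs.append(layout_path)
    else:
        layout = default_layout()

    try:
        fixations = read_fixations(fix_path, drop_invalid=config.drop_invalid)
    except Exception as exc:
        raise type(exc)(f"[stage: read_fixations] {exc}") from exc

    labeled = label_table(fixations, layout)
    artifacts: dict[str, Path] = {}
    write_table(labeled, out_dir / "labeled_fixations.csv")
    artifacts["labeled_fixations"] = out_dir / "labeled_fixations.csv"

    try:
        dwell = area_durations(labeled)
        dwell_report(
            dwell,
            out_dir / "dwell_table.csv",
            figure_dir=(out_dir / "figures") if config.figures else None,
        )
        artifacts["dwell_table"] = out_dir / "dwell_table.csv"
    except Exception as exc:
        raise type(exc)(f"[stage: dwell_analysis] {exc}") from exc

    try:
        entropy_tab = trial_entropy(labeled, pi_mode=config.pi_mode)
        entropy_tab.to_csv(out_dir / "entropy_table.csv", index=False)
        artifacts["entropy_table"] = out_dir / "entropy_table.csv"
        n_flagged = int(entropy_tab["excluded"].sum())
        if n_flagged:
            logger.warning("%d trial(s) flagged with undefined entropies", n_flagged)
    except Exception as exc:
        raise type(exc)(f"[stage: markov_entropy] {exc}") from exc

    try:
        anova_results = {
            var: two_way_anova(entropy_tab, var) for var in VARIABLES
        }
        dom = dominance_table(entropy_tab)
        report = stats_report(anova_results, dom, out_dir)
        artifacts["stats_report"] = report
        artifacts["anova_Ht"] = out_dir / "anova_Ht_bits.csv"
        artifacts["anova_Hs"] = out_dir / "anova_Hs_bits.csv"
        artifacts["dominance"] = out_dir / "dominance.csv"
    except Exception as exc:
        raise type(exc)(f"[stage: cohort_stats] {exc}") from exc

    _write_manifest(out_dir, "analyze", dataclasses.asdict(config), inputs)
    artifacts["manifest"] = out_dir / "manifest.json"
    return artifacts


def run_simulate(
    config: CohortConfig, out_dir: str | Path, drop_sidecar: bool = False
) -> dict[str, Path]:
    """Generate the synthetic cohort and write it in the analysis input dialect.

    ``fixations.csv`` carries the tracker-export column names so it feeds
    straight back into :func:`run_analyze`; the intended AOI of each fixation
    and the per-trial true matrices/entropies go to sidecar files.
    """
    out_dir = Path(out_dir)
    _setup_logging(out_dir, "INFO")
    fixations, truth = simulate_cohort(config)
    export = fixations.rename(
        columns={
            "start_ms": "fixation_start_ms",
            "duration_ms": "fixation_duration_ms",
            "end_ms": "fixation_end_ms",
            "pos_x": "position_x",
            "pos_y": "position_y",
        }
    )
    sidecar_labels = export.pop("aoi_true")
    export.to_csv(out_dir / "fixations.csv", index=False)
    artifacts = {"fixations": out_dir / "fixations.csv"}
    if not drop_sidecar:
        sidecar_labels.to_frame().to_csv(out_dir / "true_labels.csv", index=False)
        truth.to_csv(out_dir / "true_trials.csv", index=False)
        artifacts["true_labels"] = out_dir / "true_labels.csv"
        artifacts["true_trials"] = out_dir / "true_trials.csv"
    cfg = dataclasses.asdict(config)
    cfg.pop("layout", None)
    _write_manifest(out_dir, "simulate", cfg, [])
    artifacts["manifest"] = out_dir / "manifest.json"
    return artifacts


def run_worked_example(pi_mode: str = "empirical", echo=print) -> dict:
    """Recompute the embedded reference trial and print Ht/Hs at 3 decimals."""
    result = worked_example.compute(pi_mode=pi_mode)
    echo(f"Ht = {result['Ht_bits']:.3f} bits")
    echo(f"Hs = {result['Hs_bits']:.3f} bits")
    return result
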