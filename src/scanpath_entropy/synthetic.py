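"""Synthetic driving-simulator cohort generator.

Emulates the structure of the tunnel-delineator study: 21 participants each
drive 3 delineator scenarios (A: wall + pavement delineators, B: pavement
only, C: none) crossed with 3 tunnel alignments (straight, left curve,
right curve), and each drive yields an AOI-labelled fixation sequence.

Each condition has a template chain over the five AOIs built as a "sticky"
mixture P = (1 - d) I + d 1 w^T: with probability 1 - d the gaze stays
where it is, otherwise the next AOI is drawn from the visit profile w.  Such
a chain has stationary law exactly w, so a condition's true stationary
entropy is H(w) and its true transition entropy is the w-weighted mean row
entropy — which makes the encoded orderings checkable in closed form.  The
profiles encode the study's qualitative findings: with both delineator types
(A) gaze concentrates on the pavement and both entropies are lowest; with no
delineators (C) gaze shifts to the central area and top wall and entropies
are highest; straight sections produce higher entropies than curves; and the
inner wall (LW on a left curve, RW on a right curve) draws extra attention.

Participants differ by Dirichlet perturbation of the template rows;
fixation durations are lognormal (median ~300 ms); a small fraction of
white-space fixations exercises the WS-exclusion path; positions are drawn
inside the layout polygon of the intended AOI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .entropy import (
    N_STATES,
    STATES,
    stationary_eigen,
    stationary_entropy,
    transition_entropy,
)
from .errors import ValidationError
from .io_aoi import ALIGNMENTS, SCENARIOS, WS, AOILayout, default_layout

__all__ = [
    "ScenarioTemplate",
    "CohortConfig",
    "make_templates",
    "perturb_matrix",
    "sample_chain",
    "simulate_trial",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ScenarioTemplate:
    """True chain for one scenario x alignment condition."""

    scenario: str
    alignment: str
    visit_profile: np.ndarray  # stationary law w over STATES
    switch_rate: float  # d: probability of redrawing the AOI from w

    @property
    def matrix(self) -> np.ndarray:
        w = self.visit_profile
        d = self.switch_rate
        return (1.0 - d) * np.eye(N_STATES) + d * np.outer(np.ones(N_STATES), w)

    def true_entropies(self) -> tuple[float, float]:
        """(Ht, Hs) of the template chain under its stationary law."""
        return (
            transition_entropy(self.matrix, self.visit_profile),
            stationary_entropy(self.visit_profile),
        )


# visit profiles over (PA, RW, LW, TW, CA) and switch rates per condition
_TEMPLATE_PARAMS: dict[tuple[str, str], tuple[tuple[float, ...], float]] = {
    ("A", "straight"): ((0.58, 0.07, 0.07, 0.10, 0.18), 0.42),
    ("A", "left_curve"): ((0.64, 0.04, 0.12, 0.07, 0.13), 0.32),
    ("A", "right_curve"): ((0.64, 0.12, 0.04, 0.07, 0.13), 0.32),
    ("B", "straight"): ((0.40, 0.08, 0.08, 0.14, 0.30), 0.50),
    ("B", "left_curve"): ((0.46, 0.05, 0.13, 0.10, 0.26), 0.38),
    ("B", "right_curve"): ((0.46, 0.13, 0.05, 0.10, 0.26), 0.38),
    ("C", "straight"): ((0.16, 0.10, 0.10, 0.28, 0.36), 0.58),
    ("C", "left_curve"): ((0.15, 0.04, 0.17, 0.24, 0.40), 0.45),
    ("C", "right_curve"): ((0.15, 0.17, 0.04, 0.24, 0.40), 0.45),
}


def make_templates() -> dict[tuple[str, str], ScenarioTemplate]:
    """The nine condition templates (3 scenarios x 3 alignments)."""
    return {
        (sc, al): ScenarioTemplate(
            scenario=sc,
            alignment=al,
            visit_profile=np.array(w),
            switch_rate=d,
        )
        for (sc, al), (w, d) in _TEMPLATE_PARAMS.items()
    }


def perturb_matrix(
    P: np.ndarray, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet-perturb each row of P around itself.

    Row i is drawn from Dirichlet(concentration * P[i]); larger
    concentration means less inter-participant variation, and
    ``concentration = inf`` returns P unchanged.  Structural zeros stay zero.
    """
    if not np.isfinite(concentration):
        return P.copy()
    if concentration <= 0:
        raise ValidationError("Dirichlet concentration must be positive")
    out = np.zeros_like(P, dtype=float)
    for i, row in enumerate(P):
        pos = row > 0
        out[i, pos] = rng.dirichlet(concentration * row[pos])
    return out


def sample_chain(
    P: np.ndarray, n: int, rng: np.random.Generator, init: np.ndarray | None = None
) -> np.ndarray:
    """Sample a length-n state-index path; init defaults to the stationary law."""
    if n < 1:
        raise ValidationError("chain length must be >= 1")
    if init is None:
        init = stationary_eigen(P)
    cdf = np.cumsum(P, axis=1)
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(N_STATES, p=init / init.sum())
    u = rng.random(n - 1)
    for t in range(1, n):
        states[t] = np.searchsorted(cdf[states[t - 1]], u[t - 1], side="right")
    return states


def _sample_in_polygon(
    poly: Polygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points strictly inside a polygon, by rejection from its bbox."""
    minx, miny, maxx, maxy = poly.bounds
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 16)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        # boundary points are excluded so the label survives any tie-break
        on_edge = shapely.intersects(poly.exterior, shapely.points(cand))
        cand = cand[keep & ~on_edge]
        take = min(len(cand), n - got)
        pts[got : got + take] = cand[:take]
        got += take
    return pts


def _white_space_points(
    layout: AOILayout, n: int, rng: np.random.Generator
) -> np.ndarray:
    union = shapely.union_all(list(layout.regions.values()))
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 16)
        cand = np.column_stack(
            [
                rng.uniform(0, layout.frame_width, m),
                rng.uniform(0, layout.frame_height, m),
            ]
        )
        keep = ~shapely.intersects(union, shapely.points(cand))
        cand = cand[keep]
        take = min(len(cand), n - got)
        pts[got : got + take] = cand[:take]
        got += take
    return pts


def simulate_trial(
    template: ScenarioTemplate,
    matrix: np.ndarray | None,
    n_fix: int,
    rng: np.random.Generator,
    layout: AOILayout | None = None,
    participant: str = "P01",
    ws_prob: float = 0.05,
    duration_median_ms: float = 300.0,
    duration_sigma: float = 0.45,
) -> pd.DataFrame:
    """One trial's fixation table (with an ``aoi_true`` sidecar column).

    ``matrix`` is the participant's (perturbed) transition matrix; None
    uses the template matrix itself.  ``n_fix`` counts the on-AOI fixations
    before WS insertion.
    """
    if n_fix < 2:
        raise ValidationError(f"n_fix must be >= 2, got {n_fix}")
    layout = layout or default_layout()
    P = template.matrix if matrix is None else matrix
    idx = sample_chain(P, n_fix, rng)
    labels = [STATES[i] for i in idx]

    # interleave white-space fixations (dashboard glances)
    if ws_prob > 0:
        out_labels: list[str] = []
        for lab in labels:
            if rng.random() < ws_prob:
                out_labels.append(WS)
            out_labels.append(lab)
    else:
        out_labels = labels

    n_total = len(out_labels)
    durations = np.maximum(
        1,
        np.round(
            rng.lognormal(np.log(duration_median_ms), duration_sigma, n_total)
        ).astype(np.int64),
    )
    gaps = rng.integers(20, 80, n_total)  # saccade gaps, ms
    starts = np.concatenate([[0], np.cumsum(durations + gaps)[:-1]])

    pos = np.empty((n_total, 2))
    arr = np.array(out_labels, dtype=object)
    for lab in set(out_labels):
        mask = arr == lab
        if lab == WS:
            pos[mask] = _white_space_points(layout, int(mask.sum()), rng)
        else:
            pos[mask] = _sample_in_polygon(
                layout.regions[lab], int(mask.sum()), rng
            )

    return pd.DataFrame(
        {
            "participant": participant,
            "scenario": template.scenario,
            "alignment": template.alignment,
            "start_ms": starts,
            "duration_ms": durations,
            "end_ms": starts + durations,
            "pos_x": np.round(pos[:, 0], 1),
            "pos_y": np.round(pos[:, 1], 1),
            "aoi_true": out_labels,
        }
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study-shaped simulation settings (defaults mirror the emulated design)."""

    n_participants: int = 21
    scenarios: tuple[str, ...] = SCENARIOS
    alignments: tuple[str, ...] = ALIGNMENTS
    concentration: float = 200.0  # Dirichlet row concentration
    n_fix_mean: float = 120.0  # Poisson mean fixations per trial
    n_fix_min: int = 10
    ws_prob: float = 0.05
    duration_median_ms: float = 300.0
    duration_sigma: float = 0.45
    seed: int = 0
    layout: AOILayout | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if not 0 <= self.ws_prob < 1:
            raise ValidationError("ws_prob must be in [0, 1)")
        if self.n_fix_mean < 2 or self.n_fix_min < 2:
            raise ValidationError("per-trial fixation counts must be >= 2")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def simulate_cohort(
    config: CohortConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full cohort.

    Returns ``(fixations, truth)``: the fixation table in the analysis input
    format (plus the ``aoi_true`` sidecar column), and a per-trial ground
    truth table with each participant's perturbed matrix (flattened columns
    ``p_<from>_<to>``) and its exact entropies under the stationary law.
    """
    config = config or CohortConfig()
    layout = config.layout or default_layout()
    rng = np.random.default_rng(config.seed)
    templates = make_templates()
    fix_frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    width = max(2, len(str(config.n_participants)))
    for p in range(1, config.n_participants + 1):
        pid = f"P{p:0{width}d}"
        for sc in config.scenarios:
            for al in config.alignments:
                tpl = templates[(sc, al)]
                P_part = perturb_matrix(tpl.matrix, config.concentration, rng)
                n_fix = max(
                    config.n_fix_min, int(rng.poisson(config.n_fix_mean))
                )
                trial = simulate_trial(
                    tpl,
                    P_part,
                    n_fix,
                    rng,
                    layout=layout,
                    participant=pid,
                    ws_prob=config.ws_prob,
                    duration_median_ms=config.duration_median_ms,
                    duration_sigma=config.duration_sigma,
                )
                fix_frames.append(trial)
                pi_true = stationary_eigen(P_part)
                row = {
                    "participant": pid,
                    "scenario": sc,
                    "alignment": al,
                    "n_fix": n_fix,
                    "Ht_true_bits": transition_entropy(P_part, pi_true),
                    "Hs_true_bits": stationary_entropy(pi_true),
                }
                for i, si in enumerate(STATES):
                    for j, sj in enumerate(STATES):
                        row[f"p_{si}_{sj}"] = P_part[i, j]
                truth_rows.append(row)
    fixations = pd.concat(fix_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return fixations, truth
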