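"""First-order Markov model of AOI scanpaths and its Shannon entropies.

A trial's fixation sequence, restricted to the five named AOIs
S = (PA, RW, LW, TW, CA), is modelled as a first-order Markov chain.  From
the consecutive-pair counts n_ij the row-stochastic transition matrix is
p_ij = n_ij / sum_j n_ij.  Two summary entropies, both in bits:

* transition entropy  Ht = -sum_i pi_i sum_j p_ij log2 p_ij — the average
  uncertainty of the next AOI given the current one;
* stationary entropy  Hs = -sum_i pi_i log2 pi_i — the entropy of the AOI
  visit distribution.

The weight vector pi is, by default, the empirical visit frequency of each
AOI within the trial ("empirical" mode); an "eigenvector" mode instead
solves pi P = pi on the chain's recurrent class.  The convention
0 * log2(0) = 0 applies throughout, so unvisited AOIs and zero transition
cells contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .errors import AmbiguityError, ValidationError
from .io_aoi import TRIAL_KEYS, WS

#: AOI state order used for all matrices and vectors.
STATES: tuple[str, ...] = ("PA", "RW", "LW", "TW", "CA")

N_STATES = len(STATES)
MAX_ENTROPY_BITS = float(np.log2(N_STATES))

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}


def build_sequence(
    table: pd.DataFrame,
    trial: tuple | None = None,
) -> list[str]:
    """Extract one trial's AOI sequence with white space removed.

    WS fixations are deleted and the sequence spliced closed, so fixations
    separated only by white space become consecutive (a PA-WS-CA run yields
    a PA -> CA transition).  Self-repeats are preserved.

    Parameters
    ----------
    table
        Labelled fixation table.
    trial
        ``(participant, scenario, alignment)`` key; None means the table
        already holds a single trial.
    """
    if "aoi" not in table.columns:
        raise ValidationError("table has no 'aoi' column; run label_table first")
    if trial is not None:
        mask = np.ones(len(table), dtype=bool)
        for col, val in zip(TRIAL_KEYS, trial):
            mask &= (table[col] == val).to_numpy()
        if not mask.any():
            raise KeyError(f"trial {trial} not present in table")
        table = table.loc[mask]
    table = table.sort_values("start_ms", kind="mergesort")
    labels = [lab for lab in table["aoi"] if lab != WS]
    unknown = set(labels) - set(STATES)
    if unknown:
        raise ValidationError(f"labels outside the AOI state set: {sorted(unknown)}")
    return labels


def transition_counts(seq: list[str]) -> np.ndarray:
    """5x5 matrix of ordered consecutive-pair counts (self-pairs included)."""
    n = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    for a, b in zip(seq[:-1], seq[1:]):
        n[_STATE_INDEX[a], _STATE_INDEX[b]] += 1
    return n


def transition_matrix(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalise a count matrix.

    Returns ``(P, zero_rows)`` where rows with no outgoing transitions are
    left all-zero and flagged in the boolean ``zero_rows`` mask (no
    pseudocounts are applied).
    """
    n = np.asarray(n)
    if (n < 0).any():
        raise ValidationError("transition counts must be nonnegative")
    rowsums = n.sum(axis=1)
    zero_rows = rowsums == 0
    P = np.zeros_like(n, dtype=float)
    nz = ~zero_rows
    P[nz] = n[nz] / rowsums[nz, None]
    return P, zero_rows


def stationary_empirical(seq: list[str]) -> np.ndarray:
    """Visit-frequency vector: pi_i = (fixations in AOI i) / len(seq)."""
    if len(seq) == 0:
        raise ValidationError("empty sequence: visit distribution undefined")
    counts = np.zeros(N_STATES)
    for lab in seq:
        counts[_STATE_INDEX[lab]] += 1
    return counts / counts.sum()


def stationary_eigen(
    P: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Stationary vector pi with pi P = pi, by power iteration.

    Only the visited states (rows with positive out-counts or with incoming
    mass) participate.  The chain restricted to those states must have a
    single closed communicating class; otherwise the stationary law is not
    unique and :class:`AmbiguityError` is raised listing the classes.
    """
    P = np.asarray(P, dtype=float)
    _check_rows(P, atol=1e-6, allow_zero_rows=True)
    visited = (P.sum(axis=1) > 0) | (P.sum(axis=0) > 0)
    if not visited.any():
        raise ValidationError("empty chain: no transitions at all")
    idx = np.flatnonzero(visited)
    sub = P[np.ix_(idx, idx)]
    adj = (sub > 0).astype(int)
    n_comp, comp = connected_components(adj, directed=True, connection="strong")
    # a class is closed iff no edge leaves it
    closed = []
    for c in range(n_comp):
        members = comp == c
        if not (sub[members][:, ~members] > 0).any():
            closed.append(c)
    if len(closed) > 1:
        classes = [
            [STATES[idx[i]] for i in np.flatnonzero(comp == c)] for c in closed
        ]
        raise AmbiguityError(
            f"reducible chain with {len(closed)} closed classes: {classes}; "
            "no unique stationary distribution"
        )
    members = comp == closed[0]
    core = sub[np.ix_(members, members)]
    core = core / core.sum(axis=1, keepdims=True)
    v = np.full(core.shape[0], 1.0 / core.shape[0])
    for _ in range(max_iter):
        nxt = v @ core
        if np.abs(nxt - v).max() < tol:
            v = nxt
            break
        v = nxt
    v = v / v.sum()
    pi = np.zeros(N_STATES)
    pi[idx[np.flatnonzero(members)]] = v
    return pi


def _check_rows(P: np.ndarray, atol: float, allow_zero_rows: bool = True) -> None:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValidationError(f"transition matrix must be square, got {P.shape}")
    if (P < 0).any():
        raise ValidationError("transition matrix has negative entries")
    rowsums = P.sum(axis=1)
    bad = ~np.isclose(rowsums, 1.0, atol=atol)
    if allow_zero_rows:
        bad &= rowsums != 0
    if bad.any():
        raise ValidationError(
            f"rows {np.flatnonzero(bad).tolist()} sum to {rowsums[bad]} "
            f"(not 1 within {atol})"
        )


def _check_prob_vector(pi: np.ndarray, atol: float) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if (pi < 0).any():
        raise ValidationError("probability vector has negative entries")
    if not np.isclose(pi.sum(), 1.0, atol=atol):
        raise ValidationError(f"probability vector sums to {pi.sum()}, not 1")
    return pi


def _xlog2x(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0 log 0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos])
    return out


def transition_entropy(P: np.ndarray, pi: np.ndarray, atol: float = 1e-6) -> float:
    """Ht = -sum_i pi_i sum_j p_ij log2 p_ij, in bits.

    Zero rows (states never left) contribute zero row entropy.  ``atol``
    controls row-sum validation; pass a looser value (e.g. 5e-3) for
    matrices entered at printed 3-decimal precision.
    """
    P = np.asarray(P, dtype=float)
    _check_rows(P, atol=atol, allow_zero_rows=True)
    pi = _check_prob_vector(pi, atol=atol)
    row_entropies = -_xlog2x(P).sum(axis=1)
    return float(pi @ row_entropies)


def stationary_entropy(pi: np.ndarray, atol: float = 1e-6) -> float:
    """Hs = -sum_i pi_i log2 pi_i, in bits."""
    pi = _check_prob_vector(pi, atol=atol)
    return float(-_xlog2x(pi).sum())


@dataclass(frozen=True)
class TransitionModel:
    """Fitted chain for one trial: counts, transition matrix, visit law."""

    counts: np.ndarray
    P: np.ndarray
    zero_rows: np.ndarray
    pi: np.ndarray
    mode: str
    sequence_length: int

    @property
    def Ht(self) -> float:
        return transition_entropy(self.P, self.pi)

    @property
    def Hs(self) -> float:
        return stationary_entropy(self.pi)


def fit_trial(seq: list[str], pi_mode: str = "empirical") -> TransitionModel:
    """Fit the transition model for one WS-free AOI sequence."""
    if pi_mode not in ("empirical", "eigenvector"):
        raise ValueError(f"unknown pi mode: {pi_mode!r}")
    if len(seq) < 2:
        raise ValidationError(
            f"sequence of length {len(seq)} has no transitions; entropies undefined"
        )
    n = transition_counts(seq)
    P, zero_rows = transition_matrix(n)
    if pi_mode == "empirical":
        pi = stationary_empirical(seq)
    else:
        pi = stationary_eigen(P)
    return TransitionModel(
        counts=n, P=P, zero_rows=zero_rows, pi=pi, mode=pi_mode,
        sequence_length=len(seq),
    )


#: Columns of the per-trial entropy table.
ENTROPY_COLUMNS = TRIAL_KEYS + [
    "Ht_bits",
    "Hs_bits",
    "n_fixations",
    "mode",
    "excluded",
]


def trial_entropy(table: pd.DataFrame, pi_mode: str = "empirical") -> pd.DataFrame:
    """Per-trial entropy grid over all (participant, scenario, alignment).

    Trials with fewer than two non-WS fixations have undefined entropies:
    they are kept in the output flagged ``excluded = True`` (with NA
    entropies) so that downstream group statistics can drop them explicitly.
    """
    rows = []
    for key, g in table.groupby(TRIAL_KEYS, sort=True, observed=True):
        seq = build_sequence(g)
        rec = dict(zip(TRIAL_KEYS, key))
        if len(seq) < 2:
            rec |= {
                "Ht_bits": pd.NA,
                "Hs_bits": pd.NA,
                "n_fixations": len(seq),
                "mode": pi_mode,
                "excluded": True,
            }
        else:
            model = fit_trial(seq, pi_mode=pi_mode)
            rec |= {
                "Ht_bits": model.Ht,
                "Hs_bits": model.Hs,
                "n_fixations": len(seq),
                "mode": pi_mode,
                "excluded": False,
            }
        rows.append(rec)
    return pd.DataFrame(rows, columns=ENTROPY_COLUMNS)


def read_matrix_and_vector(
    matrix_path, vector_path, atol: float = 5e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Direct-entry path: read a 5x5 matrix and 5-vector from delimited text.

    The loose default ``atol`` admits matrices printed at 3-decimal
    precision.
    """
    P = np.loadtxt(matrix_path, delimiter=",")
    pi = np.loadtxt(vector_path, delimiter=",")
    if P.shape != (N_STATES, N_STATES):
        raise ValidationError(f"expected a {N_STATES}x{N_STATES} matrix, got {P.shape}")
    if pi.shape != (N_STATES,):
        raise ValidationError(f"expected a {N_STATES}-vector, got {pi.shape}")
    _check_rows(P, atol=atol)
    _check_prob_vector(pi, atol=atol)
    return P, pi
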