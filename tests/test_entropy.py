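import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from scanpath_entropy import (
    STATES,
    build_sequence,
    fit_trial,
    make_templates,
    sample_chain,
    stationary_eigen,
    stationary_empirical,
    stationary_entropy,
    transition_counts,
    transition_entropy,
    transition_matrix,
    trial_entropy,
)
from scanpath_entropy import worked_example
from scanpath_entropy.errors import AmbiguityError, ValidationError
from scanpath_entropy.entropy import MAX_ENTROPY_BITS, read_matrix_and_vector

from conftest import make_labeled
from oracles import brute_entropies

IDX = {s: i for i, s in enumerate(STATES)}


class TestBuildSequence:
    def test_white_space_spliced_out(self):
        t = make_labeled(["PA", "WS", "CA"])
        assert build_sequence(t) == ["PA", "CA"]

    def test_all_white_space_gives_empty_sequence(self):
        assert build_sequence(make_labeled(["WS", "WS"])) == []

    def test_self_repeats_preserved(self):
        assert build_sequence(make_labeled(["PA", "PA", "CA"])) == ["PA", "PA", "CA"]

    def test_unknown_trial_key_raises(self):
        t = make_labeled(["PA", "CA"])
        with pytest.raises(KeyError):
            build_sequence(t, trial=("P99", "A", "straight"))

    def test_trial_key_selects_one_trial(self):
        t = pd.concat(
            [
                make_labeled(["PA", "CA"], participant="P01"),
                make_labeled(["TW", "TW", "TW"], participant="P02"),
            ],
            ignore_index=True,
        )
        assert build_sequence(t, trial=("P02", "A", "straight")) == ["TW"] * 3


class TestCountsAndMatrix:
    def test_hand_counted_pairs(self):
        n = transition_counts(["PA", "PA", "CA", "PA"])
        assert n[IDX["PA"], IDX["PA"]] == 1
        assert n[IDX["PA"], IDX["CA"]] == 1
        assert n[IDX["CA"], IDX["PA"]] == 1
        assert n.sum() == 3

    @pytest.mark.parametrize("seq", [[], ["PA"]])
    def test_too_short_sequences_give_zero_counts(self, seq):
        assert transition_counts(seq).sum() == 0

    def test_asymmetric_pair_counts(self):
        n = transition_counts(["PA", "CA", "PA", "CA"])
        assert n[IDX["PA"], IDX["CA"]] == 2
        assert n[IDX["CA"], IDX["PA"]] == 1

    def test_row_normalisation(self):
        n = np.zeros((5, 5), dtype=int)
        n[0, :2] = [2, 0]
        n[1, :2] = [1, 1]
        P, zero = transition_matrix(n)
        assert P[0, 0] == 1.0 and P[1, 0] == P[1, 1] == 0.5
        assert zero.tolist() == [False, False, True, True, True]

    def test_all_zero_counts_flag_every_row(self):
        P, zero = transition_matrix(np.zeros((5, 5), dtype=int))
        assert (P == 0).all() and zero.all()

    def test_printed_first_row_of_reference_matrix(self):
        n = np.zeros((5, 5), dtype=int)
        n[0] = [30, 3, 2, 4, 6]
        P, _ = transition_matrix(n)
        assert np.round(P[0], 3).tolist() == [0.667, 0.067, 0.044, 0.089, 0.133]


class TestStationary:
    def test_empirical_visit_frequencies(self):
        pi = stationary_empirical(["PA", "PA", "CA", "PA"])
        assert pi[IDX["PA"]] == 0.75 and pi[IDX["CA"]] == 0.25

    def test_single_state_is_point_mass(self):
        assert stationary_empirical(["PA"]).tolist() == [1, 0, 0, 0, 0]

    def test_equal_counts_give_uniform(self):
        assert np.allclose(stationary_empirical(list(STATES)), 0.2)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            stationary_empirical([])

    def test_symmetric_two_state_chain(self):
        P = np.zeros((5, 5))
        P[0, :2] = [0.9, 0.1]
        P[1, :2] = [0.1, 0.9]
        pi = stationary_eigen(P)
        assert np.allclose(pi[:2], 0.5, atol=1e-9)

    def test_five_cycle_is_uniform(self):
        P = np.roll(np.eye(5), 1, axis=1)
        assert np.allclose(stationary_eigen(P), 0.2, atol=1e-9)

    def test_reference_matrix_stationary_close_to_printed_vector(self):
        P = worked_example.transition_matrix_printed()
        P = P / P.sum(axis=1, keepdims=True)
        pi = stationary_eigen(P)
        assert np.abs(pi - worked_example.PI).max() < 0.01

    def test_two_closed_classes_is_ambiguous(self):
        P = np.eye(5)
        with pytest.raises(AmbiguityError):
            stationary_eigen(P)


class TestEntropies:
    def test_reference_example_values(self):
        res = worked_example.compute()
        assert round(res["Ht_bits"], 3) == 1.593
        assert round(res["Hs_bits"], 3) == 2.098

    def test_uniform_matrix_maximises_transition_entropy(self):
        P = np.full((5, 5), 0.2)
        pi = np.array([0.5, 0.2, 0.1, 0.1, 0.1])
        assert transition_entropy(P, pi) == pytest.approx(math.log2(5))

    def test_permutation_matrix_is_deterministic(self):
        P = np.roll(np.eye(5), 2, axis=1)
        assert transition_entropy(P, np.full(5, 0.2)) == 0.0

    def test_point_mass_has_zero_entropy(self):
        assert stationary_entropy(np.array([1, 0, 0, 0, 0.0])) == 0.0

    def test_uniform_has_maximal_entropy(self):
        assert stationary_entropy(np.full(5, 0.2)) == pytest.approx(math.log2(5))

    def test_invalid_rows_rejected(self):
        P = np.full((5, 5), 0.3)
        with pytest.raises(ValidationError):
            transition_entropy(P, np.full(5, 0.2))

    def test_loose_tolerance_admits_printed_matrices(self):
        P = worked_example.transition_matrix_printed()  # one row sums to 1.001
        with pytest.raises(ValidationError):
            transition_entropy(P, worked_example.PI)
        val = transition_entropy(P, worked_example.PI, atol=5e-3)
        assert 0 < val < MAX_ENTROPY_BITS

    def test_unnormalised_vector_rejected(self):
        with pytest.raises(ValidationError):
            stationary_entropy(np.array([0.5, 0.4, 0, 0, 0]))

    def test_direct_entry_files(self, tmp_path):
        np.savetxt(tmp_path / "P.csv", worked_example.transition_matrix_printed(),
                   delimiter=",", fmt="%.3f")
        np.savetxt(tmp_path / "pi.csv", worked_example.PI, delimiter=",", fmt="%.3f")
        P, pi = read_matrix_and_vector(tmp_path / "P.csv", tmp_path / "pi.csv")
        assert P.shape == (5, 5) and pi.shape == (5,)


def test_exhaustive_oracle_agreement_three_symbols():
    """Counts, P, pi, Ht, Hs match naive enumeration on all short sequences."""
    symbols = STATES[:3]
    for length in range(7):
        for seq in itertools.product(symbols, repeat=length):
            seq = list(seq)
            n_o, P_o, pi_o, ht_o, hs_o = brute_entropies(seq, STATES)
            n = transition_counts(seq)
            P, _ = transition_matrix(n)
            for a in STATES:
                for b in STATES:
                    assert n[IDX[a], IDX[b]] == n_o[(a, b)]
                    assert P[IDX[a], IDX[b]] == pytest.approx(P_o[(a, b)])
            if not seq:
                continue
            pi = stationary_empirical(seq)
            for a in STATES:
                assert pi[IDX[a]] == pytest.approx(pi_o[a])
            assert transition_entropy(P, pi) == pytest.approx(ht_o)
            assert stationary_entropy(pi) == pytest.approx(hs_o)


@given(st.lists(st.sampled_from(STATES), min_size=2, max_size=40), st.permutations(range(5)))
def test_relabeling_aois_leaves_entropies_unchanged(seq, perm):
    relabel = {STATES[i]: STATES[perm[i]] for i in range(5)}
    model = fit_trial(seq)
    permuted = fit_trial([relabel[s] for s in seq])
    assert permuted.Ht == pytest.approx(model.Ht)
    assert permuted.Hs == pytest.approx(model.Hs)
    p = np.asarray(perm)
    assert np.allclose(permuted.P[np.ix_(p, p)], model.P)
    assert np.allclose(permuted.pi[p], model.pi)


class TestTrialEntropy:
    def test_single_aoi_trial_has_zero_entropies(self):
        tab = trial_entropy(make_labeled(["PA"] * 8))
        assert tab.loc[0, "Ht_bits"] == 0.0 and tab.loc[0, "Hs_bits"] == 0.0

    def test_short_trial_flagged_and_kept(self):
        t = pd.concat(
            [
                make_labeled(["PA", "WS"], participant="P01"),
                make_labeled(["PA", "CA", "PA"], participant="P02"),
            ],
            ignore_index=True,
        )
        tab = trial_entropy(t)
        short = tab[tab.participant == "P01"].iloc[0]
        assert short["excluded"] and pd.isna(short["Ht_bits"])
        assert not tab[tab.participant == "P02"].iloc[0]["excluded"]

    def test_cohort_grid_has_one_row_per_trial(self, small_cohort):
        _, fixations, _ = small_cohort
        fixations = fixations.rename(columns={"aoi_true": "aoi"})
        tab = trial_entropy(fixations)
        assert len(tab) == 6 * 3 * 3

    def test_plugin_estimate_converges_to_chain_truth(self):
        tpl = make_templates()[("A", "straight")]
        rng = np.random.default_rng(42)
        idx = sample_chain(tpl.matrix, 100_000, rng)
        seq = [STATES[i] for i in idx]
        model = fit_trial(seq)
        ht_true, hs_true = tpl.true_entropies()
        assert abs(model.Ht - ht_true) < 0.01
        assert abs(model.Hs - hs_true) < 0.01


def test_eigenvector_mode_conditioning_reduces_entropy():
    """At stationarity H(next | current) <= H(next): Ht <= Hs exactly."""
    rng = np.random.default_rng(9)
    for _ in range(50):
        P = rng.dirichlet(np.ones(5) * rng.uniform(0.3, 3.0), size=5)
        pi = stationary_eigen(P)
        assert transition_entropy(P, pi) <= stationary_entropy(pi) + 1e-12
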