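"""Unit and property tests for the dose-toxicity model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from titecrm import (
    DesignSpec,
    ParticipantSnapshot,
    compute_dose_labels,
    dose_toxicity_f,
    plug_in_probs,
    posterior_interval,
    posterior_mean,
    select_mtd,
    weighted_likelihood,
)

from .conftest import make_snapshots
from .oracles import grid_posterior


class TestDoseLabels:
    def test_identity_at_zero_prior_mean(self):
        np.testing.assert_allclose(
            compute_dose_labels((0.05, 0.15, 0.30), 0.0), (0.05, 0.15, 0.30)
        )

    def test_single_dose_log2_prior_mean(self):
        # solving d**exp(ln 2) = d**2 = 0.25 gives d = 0.5
        assert compute_dose_labels((0.25,), math.log(2.0))[0] == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "bad", [(0.30, 0.20), (0.1, 0.1), (0.0, 0.2), (0.2, 1.0)]
    )
    def test_invalid_skeleton_rejected_with_index(self, bad):
        with pytest.raises(ValueError, match=r"skeleton"):
            compute_dose_labels(bad, 0.0)

    @given(
        st.lists(st.floats(0.01, 0.95), min_size=1, max_size=6, unique=True),
        st.floats(-1.5, 1.5),
    )
    def test_calibration_round_trip(self, probs, prior_mean):
        """Plug-in probabilities at the prior mean reproduce the skeleton."""
        skeleton = tuple(sorted(probs))
        labels = compute_dose_labels(skeleton, prior_mean)
        np.testing.assert_allclose(
            plug_in_probs(labels, prior_mean), skeleton, rtol=0, atol=1e-12
        )


class TestDoseToxicityCurve:
    def test_known_values(self):
        assert dose_toxicity_f(0.25, 0.0) == 0.25
        assert dose_toxicity_f(0.25, math.log(2.0)) == pytest.approx(0.0625)
        assert dose_toxicity_f(0.9, 50.0) == pytest.approx(0.0, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            dose_toxicity_f(1.0, 0.0)
        with pytest.raises(ValueError):
            dose_toxicity_f(-0.1, 0.0)


def snap(label, tox, weight, pid="p", followup=50.0):
    return ParticipantSnapshot(pid, 1, label, tox, followup, weight)


class TestWeightedLikelihood:
    def test_empty_product_is_one(self):
        assert weighted_likelihood([], 1.7) == 1.0

    def test_single_nontoxic_half_weight(self):
        assert weighted_likelihood([snap(0.2, 0, 0.5)], 0.0) == pytest.approx(0.9)

    def test_reduces_to_binomial_with_full_weights(self):
        rng = np.random.default_rng(11)
        labels = compute_dose_labels((0.05, 0.12, 0.22, 0.35))
        for _ in range(20):
            snaps = make_snapshots(rng, labels, int(rng.integers(1, 10)),
                                   force_weight_one=True)
            beta = float(rng.normal(0, 1))
            x = np.array([s.dose_label for s in snaps])
            y = np.array([s.tox for s in snaps])
            f = x ** math.exp(beta)
            binomial = float(np.prod(np.where(y == 1, f, 1.0 - f)))
            assert weighted_likelihood(snaps, beta) == binomial

    def test_dlt_snapshot_requires_full_weight(self):
        with pytest.raises(ValueError, match="full weight"):
            snap(0.2, 1, 0.5)


class TestPosterior:
    def test_no_data_returns_prior_mean(self):
        assert posterior_mean([], 0.3, 1.34) == pytest.approx(0.3, abs=1e-8)

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(42)
        labels = compute_dose_labels((0.05, 0.12, 0.22, 0.35))
        for _ in range(5):
            snaps = make_snapshots(rng, labels, int(rng.integers(1, 12)))
            oracle_mean, oracle_q = grid_posterior(snaps, 0.0, 1.34)
            assert posterior_mean(snaps, 0.0, 1.34) == pytest.approx(
                oracle_mean, abs=1e-6
            )
            lo, hi = posterior_interval(snaps, 0.0, 1.34, 0.90)
            assert lo == pytest.approx(oracle_q(0.05), abs=1e-6)
            assert hi == pytest.approx(oracle_q(0.95), abs=1e-6)

    def test_toxicity_decreases_posterior_mean(self):
        # a DLT pulls exp(beta) down, pushing every fitted probability up
        rng = np.random.default_rng(3)
        labels = compute_dose_labels((0.05, 0.12, 0.22, 0.35))
        snaps = make_snapshots(rng, labels, 6)
        before = posterior_mean(snaps, 0.0, 1.34)
        after = posterior_mean(snaps + [snap(0.22, 1, 1.0, "new")], 0.0, 1.34)
        assert after < before

    def test_interval_reduces_to_prior_quantiles_without_data(self):
        lo, hi = posterior_interval([], 0.0, 1.0, 0.90)
        assert lo == pytest.approx(-1.6448536, abs=1e-3)
        assert hi == pytest.approx(1.6448536, abs=1e-3)

    def test_intervals_nest_across_levels(self):
        lo5, hi5 = posterior_interval([], 0.0, 1.0, 0.5)
        lo9, hi9 = posterior_interval([], 0.0, 1.0, 0.9)
        assert lo9 < lo5 < hi5 < hi9

    def test_interval_width_shrinks_with_data(self):
        rng = np.random.default_rng(9)
        label = 0.22

        def width(n):
            snaps = [
                snap(label, int(rng.random() < 0.2), 1.0, f"p{j}")
                for j in range(n)
            ]
            lo, hi = posterior_interval(snaps, 0.0, 1.34, 0.90)
            return hi - lo

        assert width(100) < width(10)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            posterior_interval([], 0.0, 1.0, 1.5)


class TestPlugInAndMtd:
    def test_plug_in_squares_labels_at_log2(self):
        np.testing.assert_allclose(
            plug_in_probs((0.05, 0.15, 0.30), math.log(2.0)),
            (0.0025, 0.0225, 0.09),
        )

    def test_plug_in_monotone(self):
        pi = plug_in_probs((0.05, 0.15, 0.30), -0.7)
        assert np.all(np.diff(pi) > 0)

    @pytest.mark.parametrize(
        "pi_hat, ttl, rule, expected",
        [
            ((0.10, 0.24, 0.40), 0.25, "highest_below", 2),
            ((0.10, 0.30), 0.25, "closest", 2),
            ((0.20, 0.30), 0.25, "closest", 1),  # tie broken to lower dose
        ],
    )
    def test_selection_examples(self, pi_hat, ttl, rule, expected):
        assert select_mtd(pi_hat, ttl, rule).index == expected

    def test_all_doses_above_target_flagged(self):
        sel = select_mtd((0.30, 0.40), 0.25, "highest_below")
        assert sel.index == 1 and sel.all_above_target

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            select_mtd((), 0.25)


class TestMonotoneUpdates:
    def test_adding_dlt_never_decreases_pi_hat(self):
        rng = np.random.default_rng(7)
        design = DesignSpec(skeleton=(0.05, 0.12, 0.22, 0.35), ttl=0.25,
                            dlt_window=168.0, n_max=21)
        labels = design.dose_labels()
        for _ in range(10):
            snaps = make_snapshots(rng, labels, int(rng.integers(1, 8)))
            pi0 = plug_in_probs(labels, posterior_mean(snaps))
            extra = snap(float(labels[rng.integers(0, 4)]), 1, 1.0, "dlt")
            pi1 = plug_in_probs(labels, posterior_mean(snaps + [extra]))
            assert np.all(pi1 >= pi0 - 1e-12)

    def test_upweighting_nontoxic_never_increases_pi_hat(self):
        rng = np.random.default_rng(8)
        labels = compute_dose_labels((0.05, 0.12, 0.22, 0.35))
        for _ in range(10):
            snaps = make_snapshots(rng, labels, int(rng.integers(2, 8)))
            nontox = [i for i, s in enumerate(snaps) if s.tox == 0 and s.weight < 1]
            if not nontox:
                continue
            i = nontox[0]
            s = snaps[i]
            heavier = ParticipantSnapshot(
                s.participant_id, s.dose_index, s.dose_label, 0,
                s.followup, min(1.0, s.weight + 0.3),
            )
            pi0 = plug_in_probs(labels, posterior_mean(snaps))
            pi1 = plug_in_probs(labels, posterior_mean(snaps[:i] + [heavier] + snaps[i + 1:]))
            assert np.all(pi1 <= pi0 + 1e-12)


class TestDesignSpecValidation:
    def test_rejects_bad_ttl_and_start_dose(self):
        with pytest.raises(ValueError):
            DesignSpec(skeleton=(0.1, 0.2), ttl=1.2, dlt_window=100, n_max=10)
        with pytest.raises(ValueError):
            DesignSpec(skeleton=(0.1, 0.2), ttl=0.25, dlt_window=100, n_max=10,
                       starting_dose_index=3)
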