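"""Concentration weighting, MuSyC fitting and synergy-mode labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synscore import (
    DataError,
    DegenerateCurveError,
    DrugSpec,
    InsufficientDataError,
    MuSyCFit,
    SimulationSpec,
    classify_synergy_mode,
    dose_weight,
    fit_block_curves,
    fit_musyc,
    make_block,
    musyc_response,
    simulate_block,
    summarize_surface,
    synergy_surface,
    weighted_surface,
)

GRID8 = tuple(np.concatenate([[0.0], np.geomspace(0.03, 30.0, 7)]))


class TestDoseWeight:
    def test_baseline_weight_is_one(self):
        assert dose_weight([0, 0], [0, 0]) == pytest.approx(1.0)

    def test_half_inhibition_gives_sqrt_half(self):
        assert dose_weight([50], [0]) == pytest.approx(np.sqrt(0.5), abs=1e-4)

    def test_saturated_single_agent_zeroes_weight(self):
        assert dose_weight([100, 20], [0, 0]) == pytest.approx(0.0)

    def test_clamping_of_out_of_range_values(self):
        # stimulation (y < l) cannot push the weight above 1,
        # super-inhibition (y > 100) cannot push it below 0
        assert dose_weight([-40, 0], [0, 0]) == pytest.approx(1.0)
        assert dose_weight([130, 0], [0, 0]) == pytest.approx(0.0)

    def test_degenerate_asymptote_rejected(self):
        with pytest.raises(DegenerateCurveError):
            dose_weight([50], [100.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            dose_weight([50, 50], [0])


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    y=st.lists(st.floats(-50, 150), min_size=1, max_size=4),
    l=st.floats(-50, 50),
)
def test_weight_always_in_unit_interval_and_monotone(y, l):
    w = dose_weight(y, [l] * len(y))
    assert 0.0 <= w <= 1.0
    # raising any single-agent response cannot raise the weight
    bumped = list(y)
    bumped[0] += 10.0
    assert dose_weight(bumped, [l] * len(y)) <= w + 1e-12


class TestWeightedSurface:
    def test_unit_weights_preserve_score(self):
        # single agents flat at l=0 -> every weight is 1
        block = make_block(
            ["A", "B"],
            [(0, 0.1, 0.3, 1, 3), (0, 0.1, 0.3, 1, 3)],
            np.zeros((5, 5)),
        )
        block.response[1:, 1:] = 10.0  # constant pure-synergy interior
        curves = fit_block_curves(block, warn_poor_fit=False)
        surf = synergy_surface(block, "bliss", curves)
        surf = weighted_surface(surf, curves, block)
        np.testing.assert_allclose(surf.weight, 1.0, atol=1e-6)
        s = summarize_surface(surf)
        assert s.weighted_mean_delta == pytest.approx(10.0, abs=1e-6)

    def test_low_dose_synergy_outranks_high_dose_synergy(self):
        """Identical delta tensors score higher when the synergy sits where
        single-agent responses are low."""
        spec = SimulationSpec(
            drugs=(DrugSpec("A", 0, 95, 1.0, 1.2),
                   DrugSpec("B", 0, 90, 0.5, 1.0)),
            dose_grids=((0, 0.05, 0.15, 0.5, 1.5, 5.0),) * 2,
            null_model="bliss",
            seed=9,
        )
        base, _ = simulate_block(spec)
        delta = np.zeros((5, 5))
        low, high = base.copy(), base.copy()
        low_patch = np.zeros((5, 5))
        low_patch[:2, :2] = 15.0
        high_patch = np.zeros((5, 5))
        high_patch[-2:, -2:] = 15.0
        low.response[low.interior_index] += low_patch
        high.response[high.interior_index] += high_patch

        scores = {}
        for name, blk in [("low", low), ("high", high)]:
            curves = fit_block_curves(blk, warn_poor_fit=False)
            surf = synergy_surface(blk, "bliss", curves)
            surf = weighted_surface(surf, curves, blk)
            scores[name] = summarize_surface(surf).weighted_mean_delta
        assert scores["low"] > scores["high"]

    def test_weighted_score_bounded_by_max_delta(self, bliss_block):
        block, _ = bliss_block
        curves = fit_block_curves(block)
        surf = weighted_surface(
            synergy_surface(block, "hsa", curves), curves, block
        )
        s = summarize_surface(surf)
        assert abs(s.weighted_mean_delta) <= np.abs(surf.delta).max() + 1e-9

    def test_sign_preserved_for_uniform_delta(self):
        block = make_block(
            ["A", "B"],
            [(0, 0.1, 0.3, 1, 3), (0, 0.1, 0.3, 1, 3)],
            np.zeros((5, 5)),
        )
        block.response[1:, 1:] = -8.0
        curves = fit_block_curves(block, warn_poor_fit=False)
        surf = weighted_surface(
            synergy_surface(block, "bliss", curves), curves, block
        )
        s = summarize_surface(surf)
        assert s.weighted_mean_delta < 0


def musyc_block(alpha, beta, noise_sd=2.0, seed=11, e1=80.0, e2=70.0):
    spec = SimulationSpec(
        drugs=(DrugSpec("A", 0, e1, 1.0, 1.0),
               DrugSpec("B", 0, e2, 0.5, 1.5)),
        dose_grids=(GRID8, GRID8),
        null_model="musyc",
        musyc_params=(alpha, alpha, beta),
        noise_sd=noise_sd,
        seed=seed,
    )
    return simulate_block(spec)[0]


class TestMuSyC:
    def test_null_surface_is_independence_product(self):
        # alpha = 1 decouples the two binding processes
        d1, d2 = 2.0, 0.7
        got = musyc_response(d1, d2, 0.0, 0.8, 0.6, 0.8, 1.0, 0.5, 1.0, 1.5)
        f1 = (d1 / 1.0) ** 1.0
        f2 = (d2 / 0.5) ** 1.5
        p1 = f1 / (1 + f1)
        p2 = f2 / (1 + f2)
        want = (
            0.8 * p1 * (1 - p2) + 0.6 * (1 - p1) * p2 + 0.8 * p1 * p2
        )
        assert got == pytest.approx(want, abs=1e-12)

    def test_parameter_recovery_with_interaction(self):
        fit = fit_musyc(musyc_block(alpha=5.0, beta=0.2))
        assert abs(np.log10(fit.alpha_12) - np.log10(5)) <= 0.3
        assert abs(np.log10(fit.alpha_21) - np.log10(5)) <= 0.3
        assert fit.beta == pytest.approx(0.2, abs=0.05)

    def test_null_recovery(self):
        fit = fit_musyc(musyc_block(alpha=1.0, beta=0.0, seed=12))
        assert abs(np.log10(fit.alpha_12 * fit.alpha_21)) / 2 <= 0.1
        assert abs(fit.beta) <= 0.03

    def test_three_dose_block_rejected(self):
        block = make_block(
            ["A", "B"], [(0, 1, 3), (0, 1, 3)], np.zeros((3, 3))
        )
        with pytest.raises(InsufficientDataError):
            fit_musyc(block)

    def test_non_sigmoidal_monotherapy_warns_but_fits(self):
        block = musyc_block(alpha=1.0, beta=0.0, noise_sd=0.0, seed=1)
        rng = np.random.default_rng(0)
        block.response[1:, 0] = rng.uniform(-30, 120, block.shape[0] - 1)
        fit = fit_musyc(block)
        assert fit.quality_warning


class TestModeClassification:
    @pytest.mark.parametrize(
        "a12,a21,beta,mode",
        [
            (5.0, 5.0, 0.0, "potency_synergy"),
            (1.0, 1.0, 0.2, "efficacy_synergy"),
            (1.0, 1.0, 0.0, "none"),
            (5.0, 5.0, 0.2, "both"),
            (0.1, 0.1, 0.0, "antagonism_potency"),
            (1.0, 1.0, -0.2, "antagonism_efficacy"),
            (5.0, 5.0, -0.2, "mixed"),
            (0.1, 0.1, 0.2, "mixed"),
        ],
    )
    def test_label_lattice(self, a12, a21, beta, mode):
        fit = MuSyCFit(
            drugs=("A", "B"), E0=0, E1=0.8, E2=0.7,
            E3=max(0.8, 0.7) + beta, C1=1, C2=1, h1=1, h2=1,
            alpha_12=a12, alpha_21=a21, beta=beta, fit_rss=0.0,
        )
        assert classify_synergy_mode(fit) == mode

    def test_within_tolerance_is_inactive(self):
        fit = MuSyCFit(
            drugs=("A", "B"), E0=0, E1=0.8, E2=0.7, E3=0.8,
            C1=1, C2=1, h1=1, h2=1,
            alpha_12=10**0.09, alpha_21=10**0.09, beta=0.049, fit_rss=0.0,
        )
        # just inside both tolerances: neither axis fires
        assert classify_synergy_mode(fit) == "none"
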