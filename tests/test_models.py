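"""Reference-model expected effects, surfaces, consensus and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synscore import (
    DataError,
    DegenerateCurveError,
    DoseResponseCurve,
    DrugSpec,
    InsufficientDataError,
    SimulationSpec,
    consensus_surface,
    expected_bliss,
    expected_hsa,
    expected_loewe,
    fit_block_curves,
    inverse_dose,
    make_block,
    predict_response,
    simulate_block,
    summarize_surface,
    synergy_surface,
    zip_surface,
)

UNIT = DoseResponseCurve("A", 0.0, 100.0, 1.0, 1.0)


class TestBliss:
    def test_two_half_effects_combine_to_75(self):
        assert expected_bliss([50, 50]) == pytest.approx(75.0)

    def test_three_half_effects_combine_to_87_5(self):
        assert expected_bliss([50, 50, 50]) == pytest.approx(87.5)

    @pytest.mark.parametrize("y", [0.0, 13.0, 62.5, 100.0])
    def test_zero_is_identity_element(self, y):
        assert expected_bliss([0.0, y]) == pytest.approx(y)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            expected_bliss([])

    def test_values_clamped_into_unit_survival(self):
        # stimulation (y < 0) contributes as 0; super-inhibition as 100
        assert expected_bliss([-30.0, 50.0]) == pytest.approx(50.0)
        assert expected_bliss([130.0, 50.0]) == pytest.approx(100.0)


class TestHSA:
    def test_max_of_singles(self):
        assert expected_hsa([30, 60]) == pytest.approx(60.0)

    def test_negative_values_allowed(self):
        assert expected_hsa([-10, 20]) == pytest.approx(20.0)

    def test_repeated_value_is_itself(self):
        assert expected_hsa([17.0] * 4) == pytest.approx(17.0)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            expected_hsa([])


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    y=st.lists(st.floats(0, 100), min_size=2, max_size=4),
)
def test_hsa_never_exceeds_bliss_on_unit_range(y):
    assert expected_hsa(y) <= expected_bliss(y) + 1e-9


class TestLoewe:
    def test_sham_combination_at_ec50_each(self):
        # a drug combined with itself at (1, 1) == single dose 2:
        # y = 100 * 2 / (1 + 2)
        got = expected_loewe([UNIT, UNIT], [1.0, 1.0])
        assert got == pytest.approx(100.0 * 2.0 / 3.0, abs=1e-3)

    def test_sham_equals_summed_dose_anywhere(self):
        c = DoseResponseCurve("A", 0, 100, 0.7, 1.8)
        for d in (0.2, 0.7, 3.0):
            got = expected_loewe([c, c], [d, d])
            assert got == pytest.approx(predict_response(c, 2 * d), abs=1e-4)

    def test_single_drug_limit(self):
        c2 = DoseResponseCurve("B", 0, 100, 5.0, 1.0)
        got = expected_loewe([UNIT, c2], [1.0, 1e-9])
        assert got == pytest.approx(predict_response(UNIT, 1.0), abs=1e-3)

    def test_saturating_doses_return_min_upper_asymptote(self):
        c2 = DoseResponseCurve("B", 0, 80, 1.0, 1.0)
        assert expected_loewe([UNIT, c2], [1e6, 1e6]) == pytest.approx(80.0)

    def test_degenerate_ranges_rejected(self):
        lo = DoseResponseCurve("L", 0, 30, 1, 1)
        hi = DoseResponseCurve("H", 50, 90, 1, 1)
        with pytest.raises(DegenerateCurveError):
            expected_loewe([lo, hi], [1.0, 1.0])

    def test_bisection_matches_grid_scan_oracle(self):
        """Brute-force oracle: dense grid scan over y on random curve pairs."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            c1 = DoseResponseCurve(
                "a", rng.uniform(0, 10), rng.uniform(60, 100),
                10 ** rng.uniform(-1, 1), rng.uniform(0.5, 3),
            )
            c2 = DoseResponseCurve(
                "b", rng.uniform(0, 10), rng.uniform(60, 100),
                10 ** rng.uniform(-1, 1), rng.uniform(0.5, 3),
            )
            d1, d2 = 10 ** rng.uniform(-1, 1), 10 ** rng.uniform(-1, 1)
            lo, hi = max(c1.l, c2.l), min(c1.u, c2.u)
            ys = np.linspace(lo + 1e-9, hi - 1e-9, 10**6)
            sums = np.abs(
                d1 / np.array([inverse_dose(c1, y) for y in ys[::1000]])
                + d2 / np.array([inverse_dose(c2, y) for y in ys[::1000]])
                - 1.0
            )
            # refine around the coarse minimum at full resolution
            k = np.argmin(sums) * 1000
            fine = ys[max(k - 1000, 0): k + 1000]
            fsums = np.abs(
                d1 / np.array([inverse_dose(c1, y) for y in fine])
                + d2 / np.array([inverse_dose(c2, y) for y in fine])
                - 1.0
            )
            y_scan = fine[np.argmin(fsums)]
            y_bis = expected_loewe([c1, c2], [d1, d2])
            if y_bis < hi:  # non-saturated
                assert abs(y_bis - y_scan) <= (hi - lo) / 10**6 * 2


class TestSurfaces:
    def test_bliss_delta_zero_on_bliss_null(self, bliss_block):
        block, _ = bliss_block
        surf = synergy_surface(block, "bliss", fit_block_curves(block))
        np.testing.assert_allclose(surf.delta, 0.0, atol=1e-9)

    def test_hsa_delta_nonnegative_on_bliss_null(self, bliss_block):
        block, _ = bliss_block
        surf = synergy_surface(block, "hsa", fit_block_curves(block))
        assert np.all(surf.delta >= -1e-9)

    def test_three_drug_bliss_shape(self):
        spec = SimulationSpec(
            drugs=(DrugSpec("A"), DrugSpec("B", ec50=0.5),
                   DrugSpec("C", ec50=2.0)),
            dose_grids=((0, 0.3, 1, 3),) * 3,
            null_model="bliss",
            seed=2,
        )
        block, _ = simulate_block(spec)
        surf = synergy_surface(block, "bliss", fit_block_curves(block))
        assert surf.delta.shape == (3, 3, 3)
        np.testing.assert_allclose(surf.delta, 0.0, atol=1e-9)

    def test_permutation_symmetry(self, bliss_block):
        block, _ = bliss_block
        flipped = make_block(
            drugs=block.drugs[::-1],
            dose_grid=block.dose_grid[::-1],
            response=block.response.T,
            block_id=block.block_id,
        )
        for model in ("bliss", "hsa", "loewe"):
            s1 = synergy_surface(block, model, fit_block_curves(block))
            s2 = synergy_surface(flipped, model, fit_block_curves(flipped))
            np.testing.assert_allclose(s1.expected, s2.expected.T, atol=1e-6)


class TestZip:
    def test_delta_near_zero_on_multiplicative_null(self, bliss_block):
        block, _ = bliss_block
        surf = zip_surface(block, fit_block_curves(block))
        assert np.abs(surf.delta).max() < 0.5

    def test_uniform_shift_recovered_in_mean_delta(self, bliss_block):
        block, _ = bliss_block
        shifted = block.copy()
        shifted.response[shifted.interior_index] += 15.0
        surf = zip_surface(shifted, fit_block_curves(shifted, warn_poor_fit=False))
        assert surf.delta.mean() == pytest.approx(15.0, abs=1.0)

    def test_two_dose_grid_rejected(self):
        block = make_block(
            ["A", "B"], [[0, 1], [0, 0.5, 1]], np.zeros((2, 3))
        )
        with pytest.raises(InsufficientDataError):
            zip_surface(block)

    def test_three_drug_block_rejected(self):
        block = make_block(
            ["A", "B", "C"], [[0, 1, 2]] * 3, np.zeros((3, 3, 3))
        )
        with pytest.raises(DataError):
            zip_surface(block)


class TestConsensus:
    def test_delta_is_elementwise_min_of_models(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            spec = SimulationSpec(
                drugs=(DrugSpec("A", 0, 100, 1, 1),
                       DrugSpec("B", 0, rng.uniform(70, 100), 0.5, 1.5)),
                dose_grids=((0, 0.1, 0.3, 1, 3, 10),) * 2,
                null_model="bliss",
                noise_sd=5.0,
                seed=seed,
            )
            block, _ = simulate_block(spec)
            curves = fit_block_curves(block, warn_poor_fit=False)
            cons = consensus_surface(block, curves)
            deltas = [
                synergy_surface(block, m, curves).delta
                for m in ("bliss", "loewe", "hsa")
            ]
            np.testing.assert_allclose(
                cons.delta, np.minimum.reduce(deltas), atol=1e-12
            )

    def test_expected_is_max_of_bliss_and_loewe_in_unit_range(self, bliss_block):
        block, _ = bliss_block
        curves = fit_block_curves(block)
        cons = consensus_surface(block, curves)
        b = synergy_surface(block, "bliss", curves).expected
        l = synergy_surface(block, "loewe", curves).expected
        np.testing.assert_allclose(cons.expected, np.maximum(b, l), atol=1e-9)

    def test_consensus_delta_zero_when_bliss_dominates(self):
        # For Hill slope 1 the Bliss expectation dominates Loewe, so a
        # Bliss-null block has consensus expected == Bliss expected and
        # consensus delta identically 0.
        spec = SimulationSpec(
            drugs=(DrugSpec("A", 0, 100, 1.0, 1.0),
                   DrugSpec("B", 0, 100, 0.4, 1.0)),
            dose_grids=((0, 0.1, 0.3, 1, 3, 10),) * 2,
            null_model="bliss",
            seed=4,
        )
        block, _ = simulate_block(spec)
        curves = fit_block_curves(block)
        b = synergy_surface(block, "bliss", curves).expected
        l = synergy_surface(block, "loewe", curves).expected
        assert np.all(b >= l - 1e-9)
        cons = consensus_surface(block, curves)
        np.testing.assert_allclose(cons.delta, 0.0, atol=1e-9)

    def test_consensus_mean_never_above_any_model_mean(self, bliss_block):
        block, _ = bliss_block
        curves = fit_block_curves(block)
        cons = summarize_surface(consensus_surface(block, curves)).mean_delta
        for m in ("bliss", "loewe", "hsa"):
            other = summarize_surface(synergy_surface(block, m, curves))
            assert cons <= other.mean_delta + 1e-12


class TestSummaries:
    def test_constant_delta(self, bliss_block):
        block, _ = bliss_block
        surf = synergy_surface(block, "bliss", fit_block_curves(block))
        surf.delta = np.full_like(surf.delta, 4.2)
        s = summarize_surface(surf)
        assert s.mean_delta == pytest.approx(4.2)
        assert s.msa_delta == pytest.approx(4.2)

    def test_corner_patch_msa(self):
        delta = np.zeros((5, 5))
        delta[:3, :3] = 9.0
        spec = SimulationSpec(
            drugs=(DrugSpec("A"), DrugSpec("B")),
            dose_grids=((0, 0.1, 0.3, 1, 3, 10),) * 2,
            seed=0,
        )
        block, _ = simulate_block(spec)
        surf = synergy_surface(block, "bliss", fit_block_curves(block))
        surf.delta = delta
        s = summarize_surface(surf, msa_window=3)
        assert s.msa_delta == pytest.approx(9.0)
        assert s.mean_delta == pytest.approx(81.0 / 25.0)

    def test_window_one_gives_max_cell(self):
        delta = np.arange(25, dtype=float).reshape(5, 5)
        spec = SimulationSpec(
            drugs=(DrugSpec("A"), DrugSpec("B")),
            dose_grids=((0, 0.1, 0.3, 1, 3, 10),) * 2,
            seed=0,
        )
        block, _ = simulate_block(spec)
        surf = synergy_surface(block, "bliss", fit_block_curves(block))
        surf.delta = delta
        assert summarize_surface(surf, msa_window=1).msa_delta == 24.0

    def test_oversized_window_clips_with_warning(self, bliss_block):
        block, _ = bliss_block
        surf = synergy_surface(block, "bliss", fit_block_curves(block))
        with pytest.warns(UserWarning, match="clipped"):
            s = summarize_surface(surf, msa_window=99)
        assert s.msa_delta == pytest.approx(s.mean_delta)
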