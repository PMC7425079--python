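"""Per-state and ensemble descriptor behaviour: PR_f, EEDL_n, SIEL."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sielkit import (
    EnsembleBand,
    ExcitonState,
    FragmentScheme,
    boltzmann_weights,
    classify_direction,
    eedl_bin,
    eedl_spectrum,
    participation_ratio,
    siel_bounds,
    siel_ensemble,
    siel_state,
    summarize,
)
from sielkit.descriptors import K_B_EV
from sielkit.errors import (
    DegenerateSchemeError,
    InvalidPopulationError,
    InvalidPRError,
    InvalidTemperatureError,
    SchemeError,
)

from conftest import simplex_grid


def _band(pops_list, scheme, energies=None, osc=None, mult="singlet"):
    energies = energies or [2.9] * len(pops_list)
    states = [
        ExcitonState(
            geometry_id=f"g{i}",
            state_index=1,
            multiplicity=mult,
            energy=energies[i],
            electron_pops=p,
            oscillator_strength=None if osc is None else osc[i],
        )
        for i, p in enumerate(pops_list)
    ]
    return EnsembleBand(states=states, scheme=scheme)


class TestParticipationRatio:
    @pytest.mark.parametrize(
        "pops, expected",
        [
            ((1, 0, 0, 0), 1.0),
            ((0.25, 0.25, 0.25, 0.25), 4.0),
            ((0.6, 0.3, 0.1, 0.0), 1 / (0.36 + 0.09 + 0.01)),
            ((0.5, 0.5), 2.0),
        ],
    )
    def test_known_values(self, pops, expected):
        assert participation_ratio(pops) == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self):
        e = np.array([0.3, 0.2, 0.5, 0.1])
        assert participation_ratio(e) == pytest.approx(
            participation_ratio(7.3 * e), abs=1e-12
        )

    @pytest.mark.parametrize("bad", [(0, 0, 0), (-0.1, 0.5, 0.6)])
    def test_invalid_vectors_rejected(self, bad):
        with pytest.raises(InvalidPopulationError):
            participation_ratio(bad)

    def test_bounds_on_simplex_grids(self):
        """PR_f stays within [1, n] over dense 3- and 4-simplex grids."""
        for m in (3, 4):
            grid = simplex_grid(m, step=0.01)
            grid = grid[grid.sum(axis=1) > 0]
            s = grid.sum(axis=1)
            pr = s * s / np.einsum("ij,ij->i", grid, grid)
            assert pr.min() >= 1.0 - 1e-12
            assert pr.max() <= m + 1e-12
            # spot-check the vectorized oracle against the implementation
            for row in grid[:: max(1, len(grid) // 50)]:
                assert participation_ratio(row) == pytest.approx(
                    (row.sum() ** 2) / (row**2).sum(), abs=1e-12
                )

    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8).filter(
            lambda v: sum(v) > 0
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_property(self, pops):
        pr = participation_ratio(pops)
        assert 1.0 - 1e-9 <= pr <= len(pops) + 1e-9


class TestEEDLBin:
    @pytest.mark.parametrize(
        "pr, n", [(1.0, 1), (1.2, 1), (1.49, 1), (1.5, 2), (2.51, 3), (3.999, 4)]
    )
    def test_binning(self, pr, n):
        assert eedl_bin(pr) == n

    def test_below_one_rejected(self):
        with pytest.raises(InvalidPRError):
            eedl_bin(0.8)


class TestEEDLSpectrum:
    def test_all_localized(self, ru_scheme):
        band = _band([(0, 1, 0, 0)] * 4, ru_scheme)
        assert eedl_spectrum(band) == {1: 100.0, 2: 0.0, 3: 0.0, 4: 0.0}

    def test_bin_counting(self, ru_scheme):
        # states constructed to have PR_f 1.2, 1.9, 2.2, 3.4 via direct search
        def pops_for(pr_target):
            # interpolate localized → uniform; PR is monotone on this family
            def vec(t):
                return np.array([1 - 0.75 * t, t / 4, t / 4, t / 4])

            lo, hi = 0.0, 1.0
            for _ in range(80):
                mid = (lo + hi) / 2
                if participation_ratio(vec(mid)) < pr_target:
                    lo = mid
                else:
                    hi = mid
            return vec(lo)

        targets = [1.2, 1.9, 2.2, 3.4]
        band = _band([pops_for(t) for t in targets], ru_scheme)
        for p, t in zip(band.electron_pops, targets):
            assert participation_ratio(p) == pytest.approx(t, abs=1e-9)
        assert eedl_spectrum(band) == {1: 25.0, 2: 50.0, 3: 25.0, 4: 0.0}

    def test_normalization_and_empty_high_bins(self, small_band):
        spec = eedl_spectrum(small_band, max_n=6)
        assert sum(spec.values()) == pytest.approx(100.0, abs=1e-9)
        assert spec[5] == 0.0 and spec[6] == 0.0

    def test_max_n_below_fragment_count_rejected(self, small_band):
        with pytest.raises(ValueError):
            eedl_spectrum(small_band, max_n=3)


class TestSielState:
    def test_even_delocalization_is_zero(self, ligand_scheme):
        assert siel_state((1 / 3, 1 / 3, 1 / 3), ligand_scheme) == pytest.approx(0.0)

    def test_full_attraction_lower_bound(self, ligand_scheme):
        assert siel_state((1, 0, 0), ligand_scheme) == pytest.approx(-1.0)

    def test_full_repulsion_upper_bound(self, ligand_scheme):
        assert siel_state((0, 0.5, 0.5), ligand_scheme) == pytest.approx(0.5)

    def test_metal_dropped_and_renormalized(self, ru_scheme, ligand_scheme):
        # metal population must not change SIEL over the ligand manifold
        with_metal = siel_state((0.2, 0.8 * 0.78, 0.8 * 0.11, 0.8 * 0.11), ru_scheme)
        without = siel_state((0.78, 0.11, 0.11), ligand_scheme)
        assert with_metal == pytest.approx(without, abs=1e-12)

    def test_reported_triazole_complex_value(self, ligand_scheme):
        """Merged populations of the N-triazole methyl adduct: −0.67 vs −0.656."""
        value = siel_state((0.78, 0.11, 0.11), ligand_scheme)
        assert value == pytest.approx(-0.67, abs=1e-9)
        assert value == pytest.approx(-0.656, abs=0.05)

    def test_bounds_and_extremes_on_grid(self, ligand_scheme):
        """On the 0.01-step 3-simplex: range [−1, 0.5], extremes only at the corners."""
        grid = simplex_grid(3, step=0.01)
        vals = np.array([siel_state(row, ligand_scheme) for row in grid if row.sum() > 0])
        lo, hi = siel_bounds(3)
        assert vals.min() == pytest.approx(lo) and vals.max() == pytest.approx(hi)
        for row in grid:
            v = siel_state(row, ligand_scheme)
            if v == pytest.approx(hi, abs=1e-12):
                assert row[0] == 0.0
            if v == pytest.approx(lo, abs=1e-12):
                assert row[0] == 1.0

    def test_permutation_of_unsubstituted_ligands(self, ru_scheme):
        a = siel_state((0.1, 0.5, 0.3, 0.1), ru_scheme)
        b = siel_state((0.1, 0.5, 0.1, 0.3), ru_scheme)
        assert a == pytest.approx(b, abs=1e-12)

    def test_m2_allowed_m1_rejected(self):
        two = FragmentScheme(["a", "b"], ["ligand", "ligand"], 0)
        assert siel_state((1, 0), two) == pytest.approx(-1.0)
        assert siel_state((0, 1), two) == pytest.approx(1.0)
        one = FragmentScheme(["metal", "a"], ["metal", "ligand"], 1)
        with pytest.raises(DegenerateSchemeError):
            siel_state((0.5, 0.5), one)

    def test_unmarked_scheme_rejected(self):
        scheme = FragmentScheme(["a", "b", "c"], ["ligand"] * 3)
        with pytest.raises(SchemeError):
            siel_state((0.3, 0.3, 0.4), scheme)

    def test_zero_ligand_population_rejected(self, ru_scheme):
        with pytest.raises(InvalidPopulationError):
            siel_state((1.0, 0.0, 0.0, 0.0), ru_scheme)


class TestBoltzmannWeights:
    def test_equal_energies_uniform(self):
        w = boltzmann_weights([1.0, 1.0, 1.0], 300.0)
        assert np.allclose(w, 1 / 3)

    def test_ln2_gap_gives_two_thirds(self):
        t = 300.0
        gap = K_B_EV * t * math.log(2)
        w = boltzmann_weights([0.0, gap], t)
        assert np.allclose(w, [2 / 3, 1 / 3], atol=1e-12)

    def test_low_temperature_limit(self):
        w = boltzmann_weights([0.5, 0.1, 0.9], 1e-3)
        assert np.argmax(w) == 1 and w[1] == pytest.approx(1.0)

    def test_shift_invariance_and_normalization(self):
        e = np.array([2.8, 2.95, 3.1])
        w1 = boltzmann_weights(e, 300.0)
        w2 = boltzmann_weights(e + 5.0, 300.0)
        assert np.allclose(w1, w2, atol=1e-12)
        assert w1.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(InvalidTemperatureError):
            boltzmann_weights([0.1, 0.2], 0.0)


class TestSielEnsemble:
    def test_identical_states(self, ligand_scheme):
        band = _band([(0.7, 0.2, 0.1)] * 5, ligand_scheme)
        mean, std = siel_ensemble(band)
        assert mean == pytest.approx(siel_state((0.7, 0.2, 0.1), ligand_scheme))
        assert std == pytest.approx(0.0, abs=1e-12)

    def test_two_state_arithmetic_mean(self, ligand_scheme):
        # SIEL values −0.4 and +0.2 from explicit populations
        p1 = (0.6, 0.2, 0.2)   # 0.5*0.4 − 0.6 = −0.4
        p2 = (0.2, 0.4, 0.4)   # 0.5*0.8 − 0.2 = +0.2
        band = _band([p1, p2], ligand_scheme)
        mean, std = siel_ensemble(band)
        assert mean == pytest.approx(-0.1, abs=1e-12)
        assert std == pytest.approx(0.3, abs=1e-12)

    def test_linearity_oracle(self, ligand_scheme):
        """Uniform-weight mean SIEL equals SIEL of the mean population vector.

        SIEL is linear in the normalized ligand populations, so for bands
        whose states are already normalized over the ligand manifold the
        ensemble mean commutes with the descriptor.
        """
        rng = np.random.default_rng(7)
        pops = rng.dirichlet((1.2, 0.8, 1.5), size=200)
        band = _band(list(pops), ligand_scheme)
        mean, _ = siel_ensemble(band)
        assert mean == pytest.approx(
            siel_state(pops.mean(axis=0), ligand_scheme), abs=1e-9
        )

    def test_boltzmann_weighting_tilts_toward_low_energy(self, ligand_scheme):
        p_low, p_high = (0.9, 0.05, 0.05), (0.05, 0.475, 0.475)
        band = _band([p_low, p_high], ligand_scheme, energies=[2.0, 2.5], mult="triplet")
        mean_b, _ = siel_ensemble(band, "boltzmann", temperature=300.0)
        assert mean_b == pytest.approx(siel_state(p_low, ligand_scheme), abs=1e-6)
        with pytest.raises(InvalidTemperatureError):
            siel_ensemble(band, "boltzmann")

    def test_oscillator_weighting(self, ligand_scheme):
        p1, p2 = (0.6, 0.2, 0.2), (0.2, 0.4, 0.4)
        band = _band([p1, p2], ligand_scheme, osc=[0.3, 0.1])
        mean, _ = siel_ensemble(band, "oscillator")
        expected = 0.75 * -0.4 + 0.25 * 0.2
        assert mean == pytest.approx(expected, abs=1e-12)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "value, label",
        [(-0.71, "attract"), (0.26, "repel"), (0.0, "neutral"),
         (-0.015, "neutral"), (0.021, "repel")],
    )
    def test_labels(self, value, label):
        assert classify_direction(value) == label

    def test_custom_tolerance(self):
        assert classify_direction(-0.015, tol=0.01) == "attract"


class TestSummarize:
    def test_summary_fields(self, small_band):
        summary = summarize(small_band, weighting="uniform")
        assert summary.n_states == len(small_band)
        assert sum(summary.eedl.values()) == pytest.approx(100.0, abs=1e-6)
        lo, hi = siel_bounds(small_band.scheme.n_ligands)
        assert lo <= summary.siel_mean <= hi
        d = summary.to_dict()
        assert d["eedl_1"] == summary.eedl[1]

    def test_unsubstituted_scheme_has_no_siel(self, small_band):
        plain = FragmentScheme(
            small_band.scheme.fragment_names, small_band.scheme.roles
        )
        band = EnsembleBand(states=small_band.states, scheme=plain)
        summary = summarize(band)
        assert summary.siel_mean is None and summary.siel_std is None
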