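"""Regime classification, scaling-law identities, and the necklace minimizer."""

import math
import warnings

import numpy as np
import pytest

from polyample.scaling_theory import (
    ScaleSeparationWarning,
    ScalingParameters,
    blob_sizes,
    classify_regime,
    globule_density,
    minimize_necklace,
    necklace_free_energy,
    phase_diagram,
    predict_conformation,
    rayleigh_ratio,
    regime_boundaries,
)

UFN_GRID = [(1.0, 1 / 16, 1e4), (0.7, 0.1, 1e5), (2.0, 0.05, 1e6),
            (0.5, 0.02, 1e6)]


def params(u, f, N, Lam):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ScaleSeparationWarning)
        return ScalingParameters(u=u, f=f, N=N, Lambda=Lam)


class TestGlobuleDensity:
    def test_alternating_branch(self):
        u, f = 0.8, 0.25
        assert globule_density(params(u, f, 1e5, 0.0)) == pytest.approx(
            u * u * f**1.5)

    def test_plateau_above_rhb(self):
        u, f, N = 1.0, 1 / 16, 1e4
        b = regime_boundaries(params(u, f, N, 1))
        phi_hb = (u * f * f) ** (1 / 3)
        for Lam in (b.L_rhb * 1.5, b.L_rhb * 10, b.L_rhb * 100):
            assert globule_density(params(u, f, N, Lam)) == pytest.approx(
                phi_hb)

    @pytest.mark.parametrize("u,f,N", UFN_GRID)
    def test_branch_intersections_at_crossovers(self, u, f, N):
        b = regime_boundaries(params(u, f, N, 1))
        # alternating and random branches meet exactly at L_ar
        assert u * u * f**1.5 == pytest.approx(u * f * b.L_ar)
        # random and blocky branches meet exactly at L_rhb
        assert u * f * b.L_rhb == pytest.approx((u * f * f) ** (1 / 3))

    def test_dense_limit_capped(self):
        with pytest.warns(ScaleSeparationWarning):
            assert globule_density(params(2.0, 1.0, 100, 5.0)) == 1.0


class TestRegimeBoundaries:
    @pytest.mark.parametrize("u,f,N", UFN_GRID)
    def test_ordering_for_separated_scales(self, u, f, N):
        b = regime_boundaries(params(u, f, N, 1))
        assert b.L_ar < b.L_rhb < b.L_bs < b.L_pe

    def test_rhb_equals_electrostatic_blob_charge(self):
        p = params(0.7, 0.1, 1e5, 1.0)
        assert regime_boundaries(p).L_rhb == pytest.approx(blob_sizes(p).q_e)

    @pytest.mark.parametrize("u,f,N", UFN_GRID)
    def test_bs_triple_equality(self, u, f, N):
        """At L_bs the bead charge Q/N_bead, the block charge Lambda, and
        the ionic string content f*m_str (regime-III laws) coincide."""
        L = regime_boundaries(params(u, f, N, 1)).L_bs
        p = params(u, f, N, L)
        Q = p.char_Q
        N_bead = u ** (2 / 3) * f ** (1 / 3) * L
        m_str = math.sqrt(N) / (u ** (2 / 3) * f ** (5 / 6) * math.sqrt(L))
        assert Q / N_bead == pytest.approx(L)
        assert f * m_str == pytest.approx(L)

    def test_pe_boundary_is_fN(self):
        assert regime_boundaries(params(1, 0.25, 4096, 1)).L_pe == 1024.0

    def test_collapsed_boundaries_warn(self):
        with pytest.warns(ScaleSeparationWarning):
            regime_boundaries(ScalingParameters(u=5.0, f=1.0, N=100,
                                                Lambda=0.1))


class TestRayleighRatio:
    def test_vanishes_with_blockiness(self):
        p = params(1.0, 1 / 16, 1e4, 1e-6)
        assert rayleigh_ratio(p) < 1e-4

    def test_order_unity_plateau_in_regime_II(self):
        u, f, N = 1.0, 1 / 16, 1e4
        b = regime_boundaries(params(u, f, N, 1))
        vals = [rayleigh_ratio(params(u, f, N, L))
                for L in np.linspace(b.L_ar * 1.01, b.L_rhb * 0.99, 7)]
        assert np.allclose(vals, 1.0)

    def test_unity_at_L_ar_and_large_above_rhb(self):
        u, f, N = 0.7, 0.1, 1e5
        b = regime_boundaries(params(u, f, N, 1))
        assert rayleigh_ratio(params(u, f, N, b.L_ar)) == pytest.approx(1.0)
        assert rayleigh_ratio(params(u, f, N, b.L_rhb * 50)) > 10


class TestClassifyRegime:
    def test_bracketing(self):
        u, f, N = 1.0, 1 / 16, 1e4
        assert classify_regime(params(u, f, N, 0.0)) == "I"
        assert classify_regime(params(u, f, N, 1.0)) == "II"  # 0.25 < 1 < 2.52
        assert classify_regime(params(u, f, N, 10 * f * N)) == "V"

    @pytest.mark.parametrize("u,f,N", UFN_GRID)
    def test_half_open_interval_assignment(self, u, f, N):
        b = regime_boundaries(params(u, f, N, 1))
        for L, lo, hi in zip(b.as_tuple(), "I II III IV".split(),
                             "II III IV V".split()):
            assert classify_regime(params(u, f, N, L * (1 - 1e-12))) == lo
            assert classify_regime(params(u, f, N, L)) == hi


class TestPredictConformation:
    @pytest.mark.parametrize("u,f,N", UFN_GRID)
    def test_R_continuous_at_upper_boundaries(self, u, f, N):
        b = regime_boundaries(params(u, f, N, 1))
        for L in (b.L_rhb, b.L_bs, b.L_pe):
            below = predict_conformation(params(u, f, N, L * (1 - 1e-12)))
            at = predict_conformation(params(u, f, N, L))
            assert at.R == pytest.approx(below.R, rel=1e-6)

    def test_regime_V_stretched_PE(self):
        u, f, N = 0.7, 0.1, 1e5
        pred = predict_conformation(params(u, f, N, 2 * f * N))
        assert pred.regime == "V"
        assert pred.R == pytest.approx(u ** (1 / 3) * f ** (2 / 3) * N)
        assert pred.N_bead == 0

    def test_single_bead_at_crossovers(self):
        u, f, N = 1.0, 1 / 16, 1e4
        b = regime_boundaries(params(u, f, N, 1))
        assert predict_conformation(params(u, f, N, b.L_rhb)).N_bead == \
            pytest.approx(1.0)
        near_pe = predict_conformation(params(u, f, N, b.L_pe * (1 - 1e-9)))
        assert near_pe.N_bead == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("u,f,N", UFN_GRID)
    def test_Q_bead_drop_at_III_IV(self, u, f, N):
        """Q_bead drops discontinuously by (N/g_e)^(1/9) at the migration
        boundary; it is asserted, not smoothed."""
        b = regime_boundaries(params(u, f, N, 1))
        below = predict_conformation(params(u, f, N, b.L_bs * (1 - 1e-12)))
        at = predict_conformation(params(u, f, N, b.L_bs))
        g_e = (u * f * f) ** (-2 / 3)
        assert below.Q_bead / at.Q_bead == pytest.approx((N / g_e) ** (1 / 9),
                                                         rel=1e-6)

    @pytest.mark.parametrize("u,f,N", UFN_GRID)
    def test_mass_conservation_within_factor_two(self, u, f, N):
        b = regime_boundaries(params(u, f, N, 1))
        # start above the fuzzy I/II crossover where m_str ~ m_bead
        for L in np.geomspace(b.L_ar * 2, b.L_pe * 0.9, 12):
            pred = predict_conformation(params(u, f, N, L))
            n_str = max(pred.N_bead, 1.0)
            total = pred.N_bead * pred.m_bead + n_str * pred.m_str
            assert N / 2 <= total <= 2 * N

    def test_necklace_length_laws(self):
        """L_nec equals the ideal-coil size sqrt(N) in II and the common
        u^(1/3) f^(1/6) (N Lambda)^(1/2) law in III and IV."""
        u, f, N = 0.7, 0.1, 1e5
        b = regime_boundaries(params(u, f, N, 1))
        in_II = predict_conformation(params(u, f, N, b.L_ar * 2))
        assert in_II.L_nec == pytest.approx(math.sqrt(N))
        for L in (b.L_rhb * 3, b.L_bs * 3):
            pred = predict_conformation(params(u, f, N, L))
            assert pred.L_nec == pytest.approx(
                u ** (1 / 3) * f ** (1 / 6) * math.sqrt(N * L))
            assert pred.m_str < pred.m_bead  # strings are light in II-IV


class TestNecklaceFreeEnergy:
    def test_single_bead_reduces_to_globule(self):
        p = params(1.0, 1 / 16, 1e4, 2.0)
        fe = necklace_free_energy(p, 1, 0.0)
        phi = globule_density(p)
        R = (p.N / phi) ** (1 / 3)
        assert fe.F_coul_bead == pytest.approx(p.u * p.char_Q**2 / R)
        assert fe.F_surf == pytest.approx((R * phi) ** 2)
        assert fe.F_el == fe.F_coul_rep == 0.0
        # ratio of destabilizing to stabilizing terms equals Eq-9 ratio
        assert fe.F_coul_bead / fe.F_surf == pytest.approx(rayleigh_ratio(p))

    def test_terms_nonnegative_and_mass_conserved(self):
        p = params(1.0, 1.0, 1e4, 10.0)
        fe = necklace_free_energy(p, 20, 0.4)
        for t in (fe.F_coul_bead, fe.F_surf, fe.F_el, fe.F_coul_rep):
            assert t >= 0
        assert fe.n_beads * (fe.m_bead + fe.m_str) == pytest.approx(p.N)

    def test_infeasible_partitions_raise(self):
        with pytest.raises(ValueError):
            # Lambda = f N: fully charged strings exhaust the chain mass
            necklace_free_energy(params(1.0, 1.0, 100, 100.0), 2, 0.0)
        with pytest.raises(ValueError):
            # string charge far above the block charge
            necklace_free_energy(params(1.0, 1.0, 1e4, 10.0), 1, 0.99)

    def test_charge_migrates_far_above_bs(self):
        u, f, N = 1.0, 1.0, 1e4
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ScaleSeparationWarning)
            L_bs = regime_boundaries(params(u, f, N, 1)).L_bs
        best = minimize_necklace(params(u, f, N, 5 * L_bs))
        assert best.q_str_frac > 0.5


class TestPhaseDiagram:
    def test_regime_I_radius(self):
        u, f, N = 1.0, 1 / 16, 1e4
        table = phase_diagram(u, f, N, [1e-3, 1e-2])
        assert table["R"].iloc[0] == pytest.approx(
            N ** (1 / 3) / (u ** (2 / 3) * math.sqrt(f)))

    def test_N_bead_nonmonotonic_peak_at_bs(self):
        u, f, N = 1.0, 1 / 16, 1e4
        b = regime_boundaries(params(u, f, N, 1))
        grid = np.geomspace(b.L_ar / 2, b.L_pe * 2, 400)
        table = phase_diagram(u, f, N, grid)
        peak = table.loc[table["N_bead"].idxmax(), "Lambda"]
        # the maximum sits at the grid point nearest L_bs
        nearest = grid[np.argmin(np.abs(np.log(grid / b.L_bs)))]
        assert peak == pytest.approx(nearest)
        # rises ~linearly in III, falls ~Lambda^(-1/2) in IV
        in_III = table[(table.regime == "III")]
        in_IV = table[(table.regime == "IV")]
        assert np.all(np.diff(in_III["N_bead"]) > 0)
        assert np.all(np.diff(in_IV["N_bead"]) < 0)

    def test_R_nondecreasing_above_ar(self):
        u, f, N = 0.7, 0.1, 1e5
        b = regime_boundaries(params(u, f, N, 1))
        table = phase_diagram(u, f, N, np.geomspace(b.L_ar, 2 * b.L_pe, 200))
        assert np.all(np.diff(table["R"]) >= -1e-9)

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            phase_diagram(1, 0.1, 1e4, [2.0, 1.0])
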