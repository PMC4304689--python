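"""Debye engine, effective amplitudes, hydration shell and chi scoring."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from coronafit import (ParticleSystem, ScatteringCurve, Species, TAIL_SPEC,
                       add_hydration_shell, debye_curve, effective_amplitude,
                       fit_scale_chi, harmonics_order, read_curve, write_curve)

RHO0 = 0.334


def lattice_sphere(radius=20.0, spacing=2.0):
    n = int(radius // spacing)
    ax = np.arange(-n, n + 1) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[(pts ** 2).sum(axis=1) <= radius ** 2]
    spec = Species("u", "point", n_e=1.0, v_vdw=1e-9)
    return ParticleSystem(pts, np.zeros(len(pts), dtype=np.int32), (spec,)), spacing


def exact_debye(coords, f_per_particle, q):
    """Reference O(N^2) Debye sum, independent of the histogram path."""
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    out = np.empty(len(q))
    for k, qv in enumerate(q):
        x = qv * d
        with np.errstate(invalid="ignore", divide="ignore"):
            sn = np.where(x > 0, np.sin(x) / np.where(x > 0, x, 1.0), 1.0)
        fk = f_per_particle[:, k]
        out[k] = float(fk @ sn @ fk)
    return out


class TestEffectiveAmplitude:
    def test_ch3_forward_value(self):
        f0 = effective_amplitude(TAIL_SPEC, 0.0, alpha=1.0, rho0=RHO0)
        assert f0 == pytest.approx(9 - 0.334 * 32.0, abs=1e-9)  # -1.688

    def test_ch3_gaussian_damping(self):
        f = effective_amplitude(TAIL_SPEC, 0.5, alpha=1.0, rho0=RHO0)
        expected = -1.688 * np.exp(-0.25 * 32.0 ** (2 / 3) / (4 * np.pi))
        assert f == pytest.approx(expected, rel=1e-6)
        assert f == pytest.approx(-1.38, abs=0.01)

    def test_contrast_matched_particle_vanishes_at_zero_angle(self):
        from coronafit import PseudoAtomSpec
        v = 30.0
        spec = PseudoAtomSpec("M", 1.0 * RHO0 * v, v, "tail")
        assert effective_amplitude(spec, 0.0, alpha=1.0, rho0=RHO0) == \
            pytest.approx(0.0, abs=1e-12)

    def test_protein_atom_uses_tabulated_form_factor(self):
        from coronafit.formfactors import group_form_factor
        from coronafit.structures import Atom
        at = Atom(1, "CB", "ALA", "A", 1, 0, 0, 0, element="C",
                  n_e=9.0, v_vdw=32.0)
        q = np.array([0.0, 0.3])
        f = effective_amplitude(at, q, alpha=1.0, rho0=RHO0)
        assert f[0] == pytest.approx(9 - RHO0 * 32.0, abs=1e-2)
        # the atomic part is the tabulated CH3 group factor, which decays
        fg = group_form_factor("C", 3, q)
        assert fg[0] == pytest.approx(9.0, abs=2e-2)
        assert fg[1] < fg[0]
        g = np.exp(-q[1] ** 2 * 32.0 ** (2 / 3) / (4 * np.pi))
        assert f[1] == pytest.approx(fg[1] - RHO0 * 32.0 * g, rel=1e-9)


class TestDebyeEngine:
    def test_single_particle_intensity_is_f_squared(self):
        spec = Species("u", "point", n_e=3.0, v_vdw=10.0)
        ps = ParticleSystem(np.zeros((1, 3)), np.zeros(1, dtype=np.int32), (spec,))
        q = np.linspace(0.0, 0.5, 11)
        c = debye_curve(ps, q, rho0=RHO0)
        f = effective_amplitude(spec, q, rho0=RHO0)
        np.testing.assert_allclose(c.i, f ** 2, rtol=1e-12)

    def test_two_point_beads_closed_form(self):
        # distance placed at a histogram bin centre so snapping is exact
        d = 5.05
        spec = Species("u", "point", n_e=2.0, v_vdw=1e-9)
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        ps = ParticleSystem(coords, np.zeros(2, dtype=np.int32), (spec,))
        q = np.linspace(0.0, 0.5, 26)
        c = debye_curve(ps, q, rho0=0.0)
        x = q * d
        with np.errstate(invalid="ignore"):
            sinc = np.where(x > 0, np.sin(x) / np.where(x > 0, x, 1), 1.0)
        np.testing.assert_allclose(c.i, 2 * 4 * (1 + sinc), rtol=1e-7)

    def test_lattice_sphere_matches_analytic_form_factor(self):
        ps, spacing = lattice_sphere()
        r_eff = (3 * len(ps) * spacing ** 3 / (4 * np.pi)) ** (1 / 3)
        q = np.linspace(0.005, 4.0 / r_eff, 40)
        c = debye_curve(ps, q, rho0=0.0)
        x = q * r_eff
        form = (3 * (np.sin(x) - x * np.cos(x)) / x ** 3) ** 2
        np.testing.assert_allclose(c.i / c.i[0], form, rtol=0.02)

    def test_histogram_agrees_with_exact_double_sum(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(-25, 25, (500, 3))
        idx = rng.integers(0, 2, 500).astype(np.int32)
        specs = (Species("A", "point", 5.0, 10.0),
                 Species("B", "point", 3.0, 20.0))
        ps = ParticleSystem(coords, idx, specs)
        q = np.linspace(0.0, 0.5, 51)
        c = debye_curve(ps, q, rho0=RHO0)
        f = np.array([effective_amplitude(s, q, rho0=RHO0) for s in specs])
        exact = exact_debye(coords, f[idx], q)
        np.testing.assert_allclose(c.i, exact, rtol=0.005)

    def test_forward_scattering_consistency(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(-10, 10, (60, 3))
        specs = (Species("A", "point", 4.0, 8.0),)
        ps = ParticleSystem(coords, np.zeros(60, dtype=np.int32), specs)
        c = debye_curve(ps, np.array([0.0, 0.1]), rho0=RHO0)
        f0 = effective_amplitude(specs[0], 0.0, rho0=RHO0)
        assert c.i[0] == pytest.approx((60 * f0) ** 2, rel=1e-9)

    def test_intensity_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(-15, 15, (80, 3))
        specs = (Species("A", "point", 4.0, 8.0),)
        idx = np.zeros(80, dtype=np.int32)
        q = np.linspace(0.01, 0.5, 30)
        i1 = debye_curve(ParticleSystem(coords, idx, specs), q, rho0=RHO0).i
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = coords @ rot.T + np.array([5.0, -3.0, 11.0])
        i2 = debye_curve(ParticleSystem(moved, idx, specs), q, rho0=RHO0).i
        np.testing.assert_allclose(i2, i1, rtol=1e-7)


class TestHydrationShell:
    def test_zero_contrast_leaves_curve_unchanged(self):
        ps, _ = lattice_sphere(radius=10.0, spacing=2.5)
        q = np.linspace(0.01, 0.3, 20)
        base = debye_curve(ps, q, rho0=RHO0)
        shelled = add_hydration_shell(ps, thickness=3.0, drho_hyd=0.0)
        assert len(shelled) > len(ps)
        withshell = debye_curve(shelled, q, rho0=RHO0, drho_hyd=0.0)
        np.testing.assert_allclose(withshell.i, base.i, rtol=1e-12)

    def test_shell_beads_hug_the_envelope(self):
        ps, spacing = lattice_sphere(radius=10.0, spacing=2.5)
        shelled = add_hydration_shell(ps, thickness=3.0, drho_hyd=0.02)
        shell = shelled.coords[len(ps):]
        assert len(shell) > 0
        from scipy.spatial import cKDTree
        d, _ = cKDTree(ps.coords).query(shell)
        # outside the particle envelope, within thickness of it (plus the
        # voxel quantisation of the surface)
        assert np.all(d > 0)
        assert np.all(d <= 3.0 + spacing)
        # radially confined to the surface region (crevices of the coarse
        # particle lattice allow beads up to ~one spacing inside R)
        r = np.linalg.norm(shell, axis=1)
        assert np.all(r > 10.0 - spacing - 0.1) and np.all(r < 10.0 + 4.5)

    def test_shell_volume_matches_analytic_shell(self):
        ps, _ = lattice_sphere(radius=20.0, spacing=2.0)
        shelled = add_hydration_shell(ps, thickness=3.0, drho_hyd=0.02)
        n_shell = len(shelled) - len(ps)
        analytic = 4.0 / 3.0 * np.pi * (23.0 ** 3 - 20.0 ** 3)
        assert n_shell * 30.0 == pytest.approx(analytic, rel=0.10)

    def test_negative_thickness_rejected(self):
        ps, _ = lattice_sphere(radius=10.0, spacing=2.5)
        with pytest.raises(ValueError):
            add_hydration_shell(ps, thickness=-1.0)


class TestChiMachinery:
    def test_identity_gives_zero_chi_unit_scale(self):
        q = np.linspace(0.01, 0.3, 10)
        i = np.exp(-q * 10)
        exp = ScatteringCurve(q, i, sigma=0.01 * i)
        score = fit_scale_chi(exp, ScatteringCurve(q, i.copy()))
        assert score.chi == pytest.approx(0.0, abs=1e-12)
        assert score.c == pytest.approx(1.0)

    def test_pure_scale_recovered(self):
        q = np.linspace(0.01, 0.3, 10)
        i = np.exp(-q * 10)
        exp = ScatteringCurve(q, i, sigma=0.01 * i)
        score = fit_scale_chi(exp, ScatteringCurve(q, i / 2.0))
        assert score.chi == pytest.approx(0.0, abs=1e-12)
        assert score.c == pytest.approx(2.0)

    def test_three_point_hand_example(self):
        exp = ScatteringCurve([0.1, 0.2, 0.3], [10.0, 5.0, 2.0],
                              sigma=[1.0, 1.0, 1.0])
        score = fit_scale_chi(exp, np.array([9.0, 6.0, 2.0]))
        assert score.c == pytest.approx(124.0 / 121.0, rel=1e-9)   # ~1.025
        assert score.chi == pytest.approx(0.9813, abs=2e-3)        # ~0.98

    @given(st.floats(1e-3, 1e3))
    def test_chi_invariant_under_joint_rescaling(self, k):
        q = np.linspace(0.01, 0.3, 8)
        i_exp = 100 * np.exp(-q * 12) + 1.0
        i_calc = 95 * np.exp(-q * 11) + 1.2
        sigma = 0.05 * i_exp
        s1 = fit_scale_chi(ScatteringCurve(q, i_exp, sigma), i_calc)
        s2 = fit_scale_chi(ScatteringCurve(q, k * i_exp, k * sigma), i_calc)
        assert s2.chi == pytest.approx(s1.chi, rel=1e-9)
        assert s2.c == pytest.approx(k * s1.c, rel=1e-9)

    def test_error_paths(self):
        q = np.linspace(0.01, 0.3, 5)
        i = np.ones(5)
        with pytest.raises(ValueError):
            fit_scale_chi(ScatteringCurve(q, i), i)  # no sigma
        with pytest.raises(ValueError):
            ScatteringCurve(q, i, sigma=np.zeros(5))  # sigma must be > 0
        exp = ScatteringCurve(q, i, sigma=i)
        with pytest.raises(ValueError):
            fit_scale_chi(exp, ScatteringCurve(q + 1.0, i))  # out of range


class TestHarmonicsOrder:
    @pytest.mark.parametrize("qmax,dmax,expected", [
        (0.5, 100.0, 30),
        (0.0, 50.0, 5),
        (0.3, 110.0, 22),  # ceil(21.5)
    ])
    def test_formula(self, qmax, dmax, expected):
        assert harmonics_order(qmax, dmax) == expected

    def test_cap(self):
        assert harmonics_order(3.0, 1000.0) == 99


class TestCurveIO:
    def test_round_trip_and_units(self, tmp_path):
        q = np.linspace(0.01, 0.4, 15)
        curve = ScatteringCurve(q, np.exp(-q * 5), sigma=np.full(15, 0.01))
        p = tmp_path / "curve.dat"
        write_curve(curve, p, header="simulated")
        back = read_curve(p)
        np.testing.assert_allclose(back.q, curve.q, atol=1e-6)
        np.testing.assert_allclose(back.i, curve.i, rtol=1e-6)
        np.testing.assert_allclose(back.sigma, curve.sigma, rtol=1e-6)
        # nm^-1 conversion
        nm = tmp_path / "nm.dat"
        nm.write_text("# q I err\n1.0 10.0 0.1\n2.0 5.0 0.1\n")
        c = read_curve(nm, q_unit="nm")
        np.testing.assert_allclose(c.q, [0.1, 0.2])

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            ScatteringCurve([0.2, 0.1], [1.0, 1.0])
        with pytest.raises(ValueError):
            ScatteringCurve([-0.1, 0.1], [1.0, 1.0])
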