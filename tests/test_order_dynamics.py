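"""Hydrogen reconstruction, order parameters, RDFs, shells and diffusion."""

import numpy as np
import pytest

from memsalt.core_model import Frame
from memsalt.order_dynamics import (
    NM2_PER_PS_TO_1E8_CM2_S,
    ChainGeometry,
    MSDCurve,
    RDFResult,
    ShellError,
    coordination_numbers,
    diffusion_coefficient,
    msd,
    order_parameter,
    rdf,
    reconstruct_hydrogens,
)
from tests.conftest import simple_topology


def zigzag_chain(n=6, axis="z"):
    """Ideal all-trans zigzag with its long axis along z."""
    k = np.arange(n)
    pts = np.column_stack([0.0445 * (-1.0) ** k, np.zeros(n), 0.127 * k])
    return pts


class TestReconstructHydrogens:
    def test_all_trans_vectors_perpendicular_to_axis(self, make_frame, make_topology):
        pts = zigzag_chain(8)
        fr = make_frame(pts)
        top = make_topology([{"tail_carbon"}] * 8)
        geom = ChainGeometry(chains=(tuple(range(8)),))
        vecs = reconstruct_hydrogens(fr, top, geom)
        assert set(vecs) == set(range(1, 7))
        for v in vecs.values():
            assert v.shape == (2, 3)
            np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0,
                                       atol=1e-12)
            np.testing.assert_allclose(v[:, 2], 0.0, atol=1e-12)

    def test_matches_rodrigues_rotation_oracle(self, make_frame, make_topology):
        # explicit bent 3-carbon fixture; independent construction rotates
        # the in-plane bisector about the C1->C3 axis by +-54.735 deg
        pts = np.array([[0.10, 0.20, 0.00],
                        [0.21, 0.31, 0.12],
                        [0.15, 0.44, 0.25]])
        fr = make_frame(pts)
        top = make_topology([{"tail_carbon"}] * 3)
        geom = ChainGeometry(chains=((0, 1, 2),))
        got = reconstruct_hydrogens(fr, top, geom)[1]

        b1 = (pts[0] - pts[1]) / np.linalg.norm(pts[0] - pts[1])
        b2 = (pts[2] - pts[1]) / np.linalg.norm(pts[2] - pts[1])
        bis = -(b1 + b2)
        bis /= np.linalg.norm(bis)
        # rotation axis of the H-C-H plane: difference of the unit bonds
        # (exactly perpendicular to the bisector, unlike the raw C1->C3 axis
        # when bond lengths differ)
        axis = -b2 - (-b1)
        axis /= np.linalg.norm(axis)
        half = np.deg2rad(109.47 / 2.0)

        def rodrigues(v, k, t):
            return (v * np.cos(t) + np.cross(k, v) * np.sin(t)
                    + k * np.dot(k, v) * (1 - np.cos(t)))

        oracle = np.stack([rodrigues(bis, axis, +half),
                           rodrigues(bis, axis, -half)])
        # order-insensitive comparison
        d = min(np.abs(got - oracle).max(), np.abs(got - oracle[::-1]).max())
        assert d < 1e-10

    def test_sp2_vector_in_neighbor_plane(self, make_frame, make_topology):
        # sp2 carbon with 120-degree neighbors in the x-y plane
        pts = np.array([[np.cos(np.deg2rad(150)), np.sin(np.deg2rad(150)), 0.0],
                        [0.0, 0.0, 0.0],
                        [np.cos(np.deg2rad(30)), np.sin(np.deg2rad(30)), 0.0]])
        fr = make_frame(pts + 5.0)
        top = make_topology([{"tail_carbon"}] * 3)
        geom = ChainGeometry(chains=((0, 1, 2),), sp2_carbons=frozenset({1}))
        v = reconstruct_hydrogens(fr, top, geom)[1]
        assert v.shape == (1, 3)
        assert v[0, 2] == pytest.approx(0.0, abs=1e-12)  # in-plane
        np.testing.assert_allclose(v[0], [0.0, -1.0, 0.0], atol=1e-9)

    def test_short_chain_raises(self, make_frame, make_topology):
        fr = make_frame(np.zeros((2, 3)))
        top = make_topology([{"tail_carbon"}] * 2)
        with pytest.raises(ValueError):
            reconstruct_hydrogens(fr, top, ChainGeometry(chains=((0, 1),)))


class TestOrderParameter:
    def test_parallel_gives_one(self):
        assert order_parameter([np.array([[0.0, 0.0, 1.0]])]) == pytest.approx(1.0)

    def test_perpendicular_gives_minus_half(self):
        assert order_parameter([np.array([[1.0, 0.0, 0.0]])]) == pytest.approx(-0.5)

    def test_isotropic_gives_zero(self, rng):
        v = rng.standard_normal((100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        s = order_parameter([v])
        # SE of (3cos^2-1)/2 for isotropic vectors is ~sqrt(1/5)/sqrt(n)
        assert abs(s) < 3.0 * np.sqrt(0.2) / np.sqrt(100_000)

    def test_mirror_invariance(self, rng):
        v = rng.standard_normal((500, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        assert order_parameter([v]) == pytest.approx(
            order_parameter([v * np.array([1.0, 1.0, -1.0])]))


class TestRDF:
    def test_ideal_gas_flat_at_one(self, rng):
        N, L = 400, 8.0
        frames = [Frame(time=i, coords=rng.random((N, 3)) * L,
                        box=np.array([L, L, L])) for i in range(20)]
        top = simple_topology([{"na_ion"}] * 200 + [{"water_oxygen"}] * 200)
        r = rdf(frames, top, "na_ion", "water_oxygen", dr=0.02, r_max=2.5)
        sel = (r.r > 0.3) & (r.r < 2.0)
        assert r.g[sel].mean() == pytest.approx(1.0, abs=0.02)
        assert np.all(np.abs(r.g[sel] - 1.0) < 0.35)  # band test

    def test_fixed_pair_single_bin(self, make_frame):
        fr = make_frame([[1, 1, 1], [1, 1, 1.5]], box=(4.0, 4.0, 4.0))
        top = simple_topology([{"na_ion"}, {"cl_ion"}])
        r = rdf([fr], top, "na_ion", "cl_ion", dr=0.02)
        nz = np.flatnonzero(r.g > 0)
        assert len(nz) == 1
        assert r.r[nz[0]] == pytest.approx(0.51, abs=1e-9)

    def test_simple_cubic_lattice_peaks(self):
        # 4x4x4 simple cubic lattice, spacing 1 nm: shells at 1, sqrt2, ...
        pts = np.array([[x, y, z] for x in range(4) for y in range(4)
                        for z in range(4)], dtype=float) + 0.5
        fr = Frame(time=0.0, coords=pts, box=np.array([4.0, 4.0, 4.0]))
        top = simple_topology([{"na_ion"}] * 64)
        r = rdf([fr], top, "na_ion", "na_ion", dr=0.01, r_max=1.9)
        peaks = r.r[r.g > 0]
        np.testing.assert_allclose(sorted(set(np.round(peaks, 1))),
                                   [1.0, 1.4, 1.7], atol=0.06)

    def test_pair_count_conservation(self, rng):
        # integral of rho_j g(r) 4 pi r^2 dr out to the half-box undercounts
        # only the corner contributions; on a near-ideal gas it approaches
        # the expected neighbor count within the sphere
        N, L = 200, 10.0
        frames = [Frame(time=i, coords=rng.random((N, 3)) * L,
                        box=np.array([L, L, L])) for i in range(10)]
        top = simple_topology([{"na_ion"}] * N)
        r = rdf(frames, top, "na_ion", "na_ion", dr=0.05, r_max=4.0)
        count = 4 * np.pi * r.rho_j * np.trapezoid(r.r**2 * r.g, r.r)
        expected = (N - 1) * (4.0 / 3.0) * np.pi * 4.0**3 / L**3
        assert count == pytest.approx(expected, rel=0.05)


class TestCoordinationNumbers:
    def _result(self, r, g, rho=1.0, dr=None):
        dr = dr if dr is not None else float(r[1] - r[0])
        return RDFResult(r=r, g=g, rho_j=rho, dr=dr, n_i=1)

    def test_ideal_gas_sphere_volume(self):
        # g = 1 with an imposed boundary at 0.3 nm: N1 = 4/3 pi R^3 rho
        r = np.arange(0.002, 1.0, 0.002)
        g = np.ones_like(r)
        g[r <= 0.05] = 0.0  # excluded core creates the first peak edge
        bump = np.exp(-((r - 0.15) ** 2) / (2 * 0.02**2))
        dip = np.exp(-((r - 0.3) ** 2) / (2 * 0.02**2))
        res = coordination_numbers(self._result(r, g + 0.5 * bump - 0.3 * dip))
        assert res.R1 == pytest.approx(0.3, abs=0.02)
        ref = 4.0 / 3.0 * np.pi * res.R1**3  # rho = 1, g ~ 1
        assert res.N1 == pytest.approx(ref, rel=0.15)

    def test_gaussian_peak_quadrature(self):
        r = np.arange(0.002, 1.2, 0.002)
        r0, sig, A = 0.4, 0.02, 0.05  # area A on zero background
        g = A / (sig * np.sqrt(2 * np.pi)) * np.exp(-((r - r0) ** 2) / (2 * sig**2))
        res = coordination_numbers(self._result(r, g, rho=2.0))
        oracle = 4 * np.pi * 2.0 * np.trapezoid(
            r[r <= res.R1] ** 2 * g[r <= res.R1], r[r <= res.R1])
        assert res.N1 == pytest.approx(oracle, rel=1e-6)
        assert res.N1 == pytest.approx(4 * np.pi * 2.0 * r0**2 * A, rel=0.02)

    def test_shoulder_flag_and_inflection(self):
        # strictly monotone decay after the peak (no minimum): a Gaussian
        # peak plus a decreasing logistic shoulder at larger r
        r = np.arange(0.002, 1.0, 0.002)
        peak = 3.0 * np.exp(-((r - 0.2) ** 2) / (2 * 0.03**2))
        tail = 1.0 / (1.0 + np.exp((r - 0.45) / 0.05))
        g = peak + tail
        res = coordination_numbers(self._result(r, g))
        assert res.shoulder_flag
        assert 0.2 < res.R1 < 0.6  # inflection of the post-peak decay
        assert res.N1 is not None and res.N1 > 0

    def test_no_peak_raises(self):
        r = np.arange(0.002, 1.0, 0.002)
        with pytest.raises(ShellError):
            coordination_numbers(self._result(r, np.zeros_like(r)))


class TestMSD:
    def test_static_particles_zero(self, make_topology):
        top = make_topology([{"lipid"}] * 4, leaflet=np.array(
            ["upper"] * 4, dtype=object))
        frames = [Frame(time=2.0 * t, coords=np.tile([1.0, 2.0, 1.0], (4, 1)),
                        box=np.array([50.0, 50.0, 10.0])) for t in range(50)]
        curve = msd(frames, top, "upper")
        np.testing.assert_allclose(curve.msd, 0.0, atol=1e-10)

    def test_matches_brute_force_oracle(self, rng, make_topology):
        # FFT estimator vs the O(T^2) all-origins double loop
        T, M = 30, 3
        pos = np.cumsum(rng.standard_normal((T, M, 2)) * 0.1, axis=0) + 50.0
        frames = [Frame(time=2.0 * t,
                        coords=np.column_stack([pos[t], np.ones(M)]),
                        box=np.array([100.0, 100.0, 10.0])) for t in range(T)]
        top = make_topology([{"lipid"}] * M, mol_ids=np.arange(M),
                            leaflet=np.array(["upper"] * M, dtype=object))
        curve = msd(frames, top, "upper")
        oracle = np.zeros(T)
        for m in range(T):
            acc = [np.sum((pos[k + m] - pos[k]) ** 2, axis=-1)
                   for k in range(T - m)]
            oracle[m] = np.mean(acc)
        np.testing.assert_allclose(curve.msd, oracle, rtol=1e-9, atol=1e-12)

    def test_wrapped_input_detected(self, make_topology):
        coords = [np.array([[0.5, 0.5, 1.0]]), np.array([[9.5, 0.5, 1.0]])]
        frames = [Frame(time=t, coords=c, box=np.array([10.0, 10.0, 5.0]))
                  for t, c in enumerate(coords)]
        top = make_topology([{"lipid"}], leaflet=np.array(["upper"],
                                                          dtype=object))
        with pytest.raises(ValueError):
            msd(frames, top, "upper", assume_unwrapped=True)
        # with unwrapping the jump is folded to 1 nm
        curve = msd(frames, top, "upper")
        assert curve.msd[1] == pytest.approx(1.0)


class TestDiffusionCoefficient:
    def test_exact_line(self):
        lags = np.arange(0.0, 100.0, 2.0)
        d_int = 3e-5  # nm^2/ps
        curve = MSDCurve(lags=lags, msd=4 * d_int * lags, n_molecules=10)
        res = diffusion_coefficient([curve], (10.0, 90.0))
        assert res.D == pytest.approx(d_int * NM2_PER_PS_TO_1E8_CM2_S, rel=1e-9)
        assert res.error == pytest.approx(0.0, abs=1e-6)

    def test_two_leaflet_average(self):
        lags = np.arange(0.0, 100.0, 2.0)
        c1 = MSDCurve(lags=lags, msd=4 * 7.5e-6 * lags, n_molecules=10)
        c2 = MSDCurve(lags=lags, msd=4 * 8.1e-6 * lags, n_molecules=10)
        res = diffusion_coefficient([c1, c2], (10.0, 90.0))
        assert res.D == pytest.approx(7.8, rel=1e-6)

    def test_sublinear_effective_D_decreases_with_window(self):
        # MSD = c * tau^0.7: the LS slope over a later window is smaller
        lags = np.arange(0.0, 6000.0, 2.0)
        curve = MSDCurve(lags=lags, msd=0.01 * lags**0.7, n_molecules=10)
        ds = [diffusion_coefficient([curve], w).D
              for w in ((2.0, 10.0), (100.0, 500.0), (2000.0, 6000.0))]
        assert ds[0] > ds[1] > ds[2]

    def test_unit_conversion_constant(self):
        # 1 nm^2/ps = 1e-14 cm^2 / 1e-12 s = 1e-2 cm^2/s = 1e6 * 1e-8 cm^2/s
        assert NM2_PER_PS_TO_1E8_CM2_S == pytest.approx(1e6)

    def test_empty_window_raises(self):
        curve = MSDCurve(lags=np.arange(10.0), msd=np.arange(10.0),
                         n_molecules=1)
        with pytest.raises(ValueError):
            diffusion_coefficient([curve], (100.0, 200.0))
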