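import numpy as np
import pytest

from qmdmd.backend import (HBondTerm, ProtonTerm, SurrogateBackend,
                           SurrogateParams, TransferTerm, evaluate)
from qmdmd.constants import TU_FEMTOSECONDS


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def test_time_unit_close_to_nominal_50fs():
    assert TU_FEMTOSECONDS == pytest.approx(50.0, rel=0.03)


def test_gradient_matches_central_differences(mg_site, mg_backend):
    system, _ = mg_site
    rng = np.random.default_rng(1)
    h = 1e-5
    for trial in range(100):
        pos = system.positions + rng.normal(0, 0.15,
                                            size=(system.n_atoms, 3))
        e, g = mg_backend.energy_gradient(pos)
        # probe 3 random coordinates per geometry
        for _ in range(3):
            i = rng.integers(system.n_atoms)
            c = rng.integers(3)
            p = pos.copy()
            p[i, c] += h
            ep = mg_backend.energy(p)
            p[i, c] -= 2 * h
            em = mg_backend.energy(p)
            fd = (ep - em) / (2 * h)
            scale = max(1.0, np.abs(g).max())
            assert abs(g[i, c] - fd) <= 1e-4 * scale


def test_energy_rotation_translation_invariant(mg_site, mg_backend):
    system, _ = mg_site
    rng = np.random.default_rng(5)
    e0 = mg_backend.energy(system.positions)
    for _ in range(5):
        R = random_rotation(rng)
        t = rng.normal(0, 3, size=3)
        assert mg_backend.energy(system.positions @ R.T + t) == \
            pytest.approx(e0, abs=1e-9)


def test_lj_well_depth_closed_form():
    params = SurrogateParams(n_atoms=2, lj_i=np.array([0]), lj_j=np.array([1]),
                             lj_sigma=np.array([3.0]), lj_eps=np.array([0.7]),
                             morse_j=np.zeros(0, int))
    pos = np.array([[0.0, 0, 0], [3.0, 0, 0]])
    assert evaluate(params, pos, want_gradient=False) == pytest.approx(-0.7)


def test_metal_charge_deepens_attraction_and_stabilizes_reactant(mg_site):
    system, _ = mg_site
    params = system.backend_params
    pos = system.positions
    tr = params.transfer
    # metal–donor energy at fixed geometry deepens with charge
    e2 = evaluate(params.with_metal(params.metal_radius, 2.0), pos,
                  want_gradient=False)
    e3 = evaluate(params.with_metal(params.metal_radius, 3.0), pos,
                  want_gradient=False)
    assert e3 < e2
    # reactant well is stabilized relative to the product well
    def well_gap(charge):
        p = params.with_metal(params.metal_radius, charge)
        # move the methyl carbon onto each well along the S→O axis
        o, s, c = pos[tr.o], pos[tr.s], pos[tr.c]
        axis = (o - s) / np.linalg.norm(o - s)
        react = pos.copy()
        prod = pos.copy()
        prod[tr.c] = s + 2.71 * axis       # product-side geometry
        return (evaluate(p, prod, want_gradient=False)
                - evaluate(p, react, want_gradient=False))
    assert well_gap(3.0) > well_gap(2.0)


def test_two_well_shape_along_transfer_coordinate(mg_site):
    system, _ = mg_site
    params = system.backend_params
    tr = params.transfer
    pos = system.positions.copy()
    o, s = pos[tr.o], pos[tr.s]
    axis = (o - s) / np.linalg.norm(o - s)
    ts = np.linspace(1.2, 3.4, 301)            # S–C distance along the axis
    energies = []
    for t in ts:
        p = pos.copy()
        p[tr.c] = s + t * axis
        energies.append(evaluate(params, p, want_gradient=False))
    energies = np.array(energies)
    interior = energies[1:-1]
    minima = np.sum((interior < energies[:-2]) & (interior < energies[2:]))
    maxima = np.sum((interior > energies[:-2]) & (interior > energies[2:]))
    assert minima == 2 and maxima == 1


class TestPartialOptimize:
    def test_start_at_minimum_is_identity(self, mg_site, mg_backend):
        system, truth = mg_site
        free = [a.atom_id for a in system.atoms if not a.frozen]
        p0, _ = mg_backend.partial_optimize(system.positions, free, tol=1e-4)
        p1, res = mg_backend.partial_optimize(p0, free, tol=1e-4)
        assert res.converged
        assert np.max(np.linalg.norm(p1 - p0, axis=1)) < 1e-3

    def test_harmonic_well_closed_form(self):
        params = SurrogateParams(n_atoms=2,
                                 harm_i=np.array([0]), harm_j=np.array([1]),
                                 harm_r0=np.array([1.5]),
                                 harm_k=np.array([100.0]),
                                 morse_j=np.zeros(0, int))
        be = SurrogateBackend(params)
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])   # 0.5 Å off the minimum
        out, res = be.partial_optimize(pos, [1], tol=1e-8)
        assert res.converged
        assert np.linalg.norm(out[1] - out[0]) == pytest.approx(1.5, abs=1e-6)

    def test_all_frozen_is_noop_with_flag(self, mg_site, mg_backend):
        system, _ = mg_site
        out, res = mg_backend.partial_optimize(system.positions, [])
        assert np.array_equal(out, system.positions)
        assert res.message == "nothing to optimize"

    def test_energy_never_increases(self, mg_site, mg_backend):
        system, _ = mg_site
        rng = np.random.default_rng(3)
        pos = system.positions + rng.normal(0, 0.2, (system.n_atoms, 3))
        e0 = mg_backend.energy(pos)
        free = [a.atom_id for a in system.atoms if not a.frozen]
        _out, res = mg_backend.partial_optimize(pos, free, tol=1e-5)
        assert res.energy <= e0


class TestHessian:
    def test_harmonic_frequency_closed_form(self):
        k, m = 200.0, 12.011
        params = SurrogateParams(n_atoms=2,
                                 harm_i=np.array([0]), harm_j=np.array([1]),
                                 harm_r0=np.array([1.5]),
                                 harm_k=np.array([k]),
                                 morse_j=np.zeros(0, int))
        be = SurrogateBackend(params)
        pos = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        res = be.hessian(pos, [1], masses=np.array([m, m]))
        # one atom frozen: stretch frequency sqrt(k/m)/2π in cycles per t.u.
        expected = np.sqrt(k / m) / (2 * np.pi)
        assert res.frequencies.max() == pytest.approx(expected, rel=1e-4)
        assert res.n_imaginary == 0
        assert res.zpe > 0

    def test_two_well_extrema_mode_counts(self):
        # symmetric two-well term alone: the wells and the barrier top are
        # exact stationary points by construction
        a, d_os = 0.9, 4.5
        tr = TransferTerm(s=0, c=1, o=2, barrier=8.0, xi_well=a, tilt0=0.0,
                          tilt_charge=0.0, penalty_radius=0.0,
                          penalty_angle=0.0, kappa_angle=0.0, k_eta=50.0,
                          eta0=d_os)
        params = SurrogateParams(n_atoms=3, morse_j=np.zeros(0, int),
                                 transfer=tr)
        be = SurrogateBackend(params)
        masses = np.array([32.06, 12.011, 15.999])
        well = np.array([[0.0, 0, 0], [(d_os - a) / 2, 0, 0], [d_os, 0, 0]])
        res_min = be.hessian(well, [1], masses=masses)
        assert res_min.n_imaginary == 0
        top = well.copy()
        top[1, 0] = d_os / 2.0                  # ξ = 0 exactly
        res_ts = be.hessian(top, [1], masses=masses)
        assert res_ts.n_imaginary == 1

    def test_nonstationary_warning(self, mg_site, mg_backend):
        system, _ = mg_site
        pos = system.positions + 0.3
        pos[0] += 0.5
        free = [a.atom_id for a in system.atoms if not a.frozen][:4]
        rng = np.random.default_rng(0)
        pos = system.positions + rng.normal(0, 0.3, (system.n_atoms, 3))
        with pytest.warns(UserWarning, match="non-stationary"):
            res = mg_backend.hessian(pos, free, masses=system.masses)
        assert res.warning is not None


def test_params_round_trip_through_dict(mg_site):
    params = mg_site[0].backend_params
    back = SurrogateParams.from_dict(params.to_dict())
    assert np.array_equal(back.harm_r0, params.harm_r0)
    assert back.transfer.barrier == params.transfer.barrier
    assert back.proton.mu_product == params.proton.mu_product
    assert back.metal_radius == params.metal_radius
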