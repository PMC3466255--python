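"""Pluggable active-site energy backends and the built-in analytic surrogate.

The surrogate plays the role a quantum-chemistry engine plays in the full
protocol: single-point energies, gradients, partial optimization with frozen
atoms, and finite-difference Hessians with harmonic frequencies and ZPE.  It
is an analytic model, not an electronic-structure method:

* a structured elastic network (harmonic pair terms at reference distances)
  holds the scaffold so the construction geometry is a true minimum;
* metal–donor interactions are Morse wells whose equilibrium distance grows
  with the metal ionic radius and whose depth/stiffness grow with the metal
  charge — the surrogate analog of cation size and electrophilicity;
* a two-well potential along the methyl-transfer coordinate
  ξ = R(O–C) − R(S–C) (reactant ξ > 0, product ξ < 0) carries the reactive
  step.  Its barrier is inflated as the O–C–S angle departs from
  collinearity, its reactant well is stabilized by metal charge, and the
  product side is penalized by metal radius and misalignment;
* an optional proton-coupling term drags the acceptor-bound hydrogen toward
  a base site as ξ advances (the lysine-mediated proton abstraction analog).

Energies in kcal/mol, lengths in Å, masses in amu; frequencies come out in
cycles per DMD time unit (≈48.89 fs).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .constants import PLANCK_KCALMOL_TU

# eigenvalue magnitude below which a mode counts as zero (kcal/mol/Å²/amu)
ZERO_MODE_TOL = 1e-4


# ---------------------------------------------------------------------------
# parameter container


@dataclass
class HBondTerm:
    donor: int      # heavy donor atom D
    hydrogen: int   # H
    acceptor: int   # acceptor A
    d0: float = 1.90      # optimal H···A distance, Å
    sigma: float = 0.35   # Gaussian width, Å
    eps: float = 3.0      # well depth at ideal geometry, kcal/mol


@dataclass
class TransferTerm:
    """Two-well methyl-transfer term on ξ = R(O–C) − R(S–C)."""

    s: int
    c: int
    o: int
    barrier: float = 10.0        # quartic barrier height h, kcal/mol
    xi_well: float = 0.91        # |ξ| at the wells, Å
    tilt0: float = 3.0           # reactant-side stabilization Δ at q=+2
    tilt_charge: float = 8.0     # dΔ/dq, kcal/mol per unit charge
    penalty_radius: float = 10.0  # product-side penalty per Å of metal radius
    penalty_angle: float = 4.0   # product-side penalty scale vs misalignment
    kappa_angle: float = 0.5     # barrier inflation vs (1 + cos α)
    radius_ref: float = 0.72     # Mg-like reference radius, Å
    switch_width: float = 0.5    # width of the product-side switch in u = ξ/a
    k_eta: float = 40.0          # stiffness on η = R(O–C) + R(S–C)
    eta0: float = 4.51           # native η, Å


@dataclass
class ProtonTerm:
    """ξ-coupled O–H term moving the proton toward the base site."""

    o: int
    h: int
    k: float = 80.0
    mu_reactant: float = 0.98   # O–H equilibrium at the reactant well, Å
    mu_product: float = 1.80    # O–H equilibrium at the product well, Å
    switch_width: float = 0.5
    enabled: bool = True


@dataclass
class SurrogateParams:
    """All terms of the analytic surrogate, bound to system atom ids."""

    n_atoms: int
    # harmonic network: bonds, 1-3 terms, contacts, frame tethers
    harm_i: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    harm_j: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    harm_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    harm_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    # metal–donor Morse terms
    metal: int = -1
    morse_j: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    morse_offset: np.ndarray = field(default_factory=lambda: np.zeros(0))
    morse_d0: float = 40.0
    morse_a: float = 1.8
    metal_radius: float = 0.72
    metal_charge: float = 2.0
    charge_coupling: float = 0.5   # fractional deepening of D per unit charge
    # 12-6 nonbonded
    lj_i: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    lj_j: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    lj_sigma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lj_eps: np.ndarray = field(default_factory=lambda: np.zeros(0))
    hbonds: list[HBondTerm] = field(default_factory=list)
    transfer: TransferTerm | None = None
    proton: ProtonTerm | None = None
    # pairs the stepwise sampler must not give generic nonbonded shells
    # (H-bonded contacts, the transfer unit vs. the substrate)
    nb_exclusions: list = field(default_factory=list)

    def with_metal(self, radius: float, charge: float) -> "SurrogateParams":
        """New params with a different metal radius/charge (terms shared)."""
        return dataclasses.replace(self, metal_radius=float(radius),
                                   metal_charge=float(charge))

    def to_dict(self) -> dict:
        def enc(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (list, tuple)):
                return [enc(v) for v in x]
            if dataclasses.is_dataclass(x):
                return {k: enc(v) for k, v in dataclasses.asdict(x).items()}
            return x
        return {k: enc(v) for k, v in dataclasses.asdict(self).items()}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SurrogateParams":
        d = dict(d)
        for k in ("harm_i", "harm_j", "morse_j"):
            d[k] = np.asarray(d.get(k, []), dtype=int)
        for k in ("harm_r0", "harm_k", "morse_offset", "lj_sigma", "lj_eps"):
            d[k] = np.asarray(d.get(k, []), dtype=float)
        for k in ("lj_i", "lj_j"):
            d[k] = np.asarray(d.get(k, []), dtype=int)
        d["hbonds"] = [HBondTerm(**h) for h in d.get("hbonds", [])]
        if d.get("transfer"):
            d["transfer"] = TransferTerm(**d["transfer"])
        if d.get("proton"):
            d["proton"] = ProtonTerm(**d["proton"])
        d["nb_exclusions"] = [tuple(p) for p in d.get("nb_exclusions", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# evaluation helpers


def _angle_cos_grad(u, v):
    """cos of the angle between vectors u, v and its gradients d cos/du, d cos/dv."""
    cu = np.linalg.norm(u)
    cv = np.linalg.norm(v)
    c = float(u @ v) / (cu * cv)
    gu = v / (cu * cv) - c * u / cu**2
    gv = u / (cu * cv) - c * v / cv**2
    return c, gu, gv


def _proton_switch(u, width):
    return 0.5 * (1.0 - np.tanh(u / width))


def evaluate(params: SurrogateParams, pos: np.ndarray,
             active: np.ndarray | None = None,
             want_gradient: bool = True):
    """Energy (and gradient) of the surrogate at ``pos`` (n_atoms, 3).

    ``active`` is a boolean mask over atoms; a term contributes only when all
    of its atoms are active.  Inactive atoms' coordinates are ignored, which
    lets the same parameter set serve full-system, capped-cluster and
    subset-energy evaluations.
    """
    pos = np.asarray(pos, dtype=float)
    if active is None:
        active = np.ones(params.n_atoms, dtype=bool)
    E = 0.0
    grad = np.zeros_like(pos) if want_gradient else None

    def pair_block(i, j, dEdd_fn):
        nonlocal E
        mask = active[i] & active[j]
        if not np.any(mask):
            return
        ii, jj = i[mask], j[mask]
        dvec = pos[jj] - pos[ii]
        d = np.linalg.norm(dvec, axis=1)
        e_terms, dEdd = dEdd_fn(mask, d)
        E += float(np.sum(e_terms))
        if want_gradient:
            f = (dEdd / d)[:, None] * dvec   # dE/dr_j
            np.add.at(grad, jj, f)
            np.add.at(grad, ii, -f)

    # harmonic network
    if len(params.harm_i):
        def harm(mask, d):
            r0 = params.harm_r0[mask]
            k = params.harm_k[mask]
            return 0.5 * k * (d - r0) ** 2, k * (d - r0)
        pair_block(params.harm_i, params.harm_j, harm)

    # metal–donor Morse
    if len(params.morse_j) and active[params.metal]:
        D = params.morse_d0 * (1.0 + params.charge_coupling
                               * (params.metal_charge - 2.0))
        a = params.morse_a
        mi = np.full(len(params.morse_j), params.metal)

        def morse(mask, d):
            eq = params.morse_offset[mask] + params.metal_radius
            x = np.exp(-a * (d - eq))
            return D * ((1.0 - x) ** 2 - 1.0), 2.0 * D * a * x * (1.0 - x)
        pair_block(mi, params.morse_j, morse)

    # 12-6 nonbonded
    if len(params.lj_i):
        def lj(mask, d):
            s = params.lj_sigma[mask]
            e = params.lj_eps[mask]
            r6 = (s / d) ** 6
            return e * (r6**2 - 2.0 * r6), e * 12.0 * (r6 - r6**2) / d
        pair_block(params.lj_i, params.lj_j, lj)

    # H-bond wells
    for hb in params.hbonds:
        if not (active[hb.donor] and active[hb.hydrogen] and active[hb.acceptor]):
            continue
        u = pos[hb.donor] - pos[hb.hydrogen]
        v = pos[hb.acceptor] - pos[hb.hydrogen]
        dha = np.linalg.norm(v)
        c, gu, gv = _angle_cos_grad(u, v)
        f_ang = ((1.0 - c) / 2.0) ** 2
        gauss = np.exp(-((dha - hb.d0) ** 2) / (2.0 * hb.sigma**2))
        E += -hb.eps * gauss * f_ang
        if want_gradient:
            dE_ddha = -hb.eps * f_ang * gauss * (-(dha - hb.d0) / hb.sigma**2)
            dE_dc = hb.eps * gauss * (1.0 - c) / 2.0
            uhat_ha = v / dha
            grad[hb.acceptor] += dE_ddha * uhat_ha + dE_dc * gv
            grad[hb.donor] += dE_dc * gu
            grad[hb.hydrogen] += -dE_ddha * uhat_ha - dE_dc * (gu + gv)

    # two-well transfer term (+ optional proton coupling, which shares ξ)
    tr = params.transfer
    if tr is not None and active[tr.s] and active[tr.c] and active[tr.o]:
        vo = pos[tr.o] - pos[tr.c]
        vs = pos[tr.s] - pos[tr.c]
        dOC = np.linalg.norm(vo)
        dSC = np.linalg.norm(vs)
        xi = dOC - dSC
        a = tr.xi_well
        u = xi / a
        cosA, gO, gS = _angle_cos_grad(vo, vs)
        one_plus = 1.0 + cosA
        Afac = 1.0 + tr.kappa_angle * one_plus
        quart = (u * u - 1.0) ** 2
        tilt = tr.tilt0 + tr.tilt_charge * (params.metal_charge - 2.0)
        pen = (tr.penalty_radius * (params.metal_radius - tr.radius_ref)
               + tr.penalty_angle * one_plus)
        w = tr.switch_width
        th = np.tanh(u / w)
        g_sw = 0.5 * (1.0 - th)
        eta = dOC + dSC
        E += (tr.barrier * Afac * quart - 0.5 * tilt * u + pen * g_sw
              + 0.5 * tr.k_eta * (eta - tr.eta0) ** 2)

        dE_du = (tr.barrier * Afac * 4.0 * u * (u * u - 1.0) - 0.5 * tilt
                 - pen * 0.5 * (1.0 - th * th) / w)
        dE_dcos = tr.barrier * tr.kappa_angle * quart + tr.penalty_angle * g_sw

        # proton coupling rides on the same u
        pr = params.proton
        pr_active = (pr is not None and active[pr.o] and active[pr.h])
        if pr_active:
            vOH = pos[pr.h] - pos[pr.o]
            dOH = np.linalg.norm(vOH)
            if pr.enabled:
                ws = pr.switch_width
                s_hi = _proton_switch(-1.0, ws)   # value at the product well
                s_lo = _proton_switch(1.0, ws)    # value at the reactant well
                s_n = (_proton_switch(u, ws) - s_lo) / (s_hi - s_lo)
                mu = pr.mu_reactant + (pr.mu_product - pr.mu_reactant) * s_n
                dmu_du = ((pr.mu_product - pr.mu_reactant) / (s_hi - s_lo)
                          * (-0.5 * (1.0 - np.tanh(u / ws) ** 2) / ws))
            else:
                mu = pr.mu_reactant
                dmu_du = 0.0
            E += 0.5 * pr.k * (dOH - mu) ** 2
            if want_gradient:
                dE_ddOH = pr.k * (dOH - mu)
                uhat = vOH / dOH
                grad[pr.h] += dE_ddOH * uhat
                grad[pr.o] += -dE_ddOH * uhat
                dE_du += -pr.k * (dOH - mu) * dmu_du

        if want_gradient:
            dE_dxi = dE_du / a
            k_eta_f = tr.k_eta * (eta - tr.eta0)
            uo = vo / dOC
            us = vs / dSC
            grad[tr.o] += (dE_dxi + k_eta_f) * uo + dE_dcos * gO
            grad[tr.s] += (-dE_dxi + k_eta_f) * us + dE_dcos * gS
            grad[tr.c] += (-(dE_dxi + k_eta_f) * uo - (-dE_dxi + k_eta_f) * us
                           - dE_dcos * (gO + gS))

    if want_gradient:
        return E, grad
    return E


# ---------------------------------------------------------------------------
# backend contract


class EnergyBackend:
    """Active-site energy contract.

    Implementations expose ``capabilities`` and operate on a positions array
    plus an activity mask; the partition/mechanism modules wrap this for
    capped clusters.  A real quantum-chemistry engine can be adapted behind
    this interface; only the analytic surrogate ships.
    """

    capabilities: frozenset = frozenset()

    def energy(self, pos, active=None) -> float:
        raise NotImplementedError

    def gradient(self, pos, active=None) -> np.ndarray:
        raise NotImplementedError


@dataclass
class OptimizeResult:
    converged: bool
    n_iter: int
    energy: float
    max_grad: float
    message: str = ""


class SurrogateBackend(EnergyBackend):
    """Analytic surrogate PES (see module docstring)."""

    capabilities = frozenset({"energy", "gradient", "partial_optimize", "hessian"})

    def __init__(self, params: SurrogateParams):
        self.params = params

    def with_metal(self, radius: float, charge: float) -> "SurrogateBackend":
        return SurrogateBackend(self.params.with_metal(radius, charge))

    def energy(self, pos, active=None) -> float:
        return evaluate(self.params, pos, active, want_gradient=False)

    def gradient(self, pos, active=None) -> np.ndarray:
        return evaluate(self.params, pos, active, want_gradient=True)[1]

    def energy_gradient(self, pos, active=None):
        return evaluate(self.params, pos, active, want_gradient=True)

    # -- partial optimization -------------------------------------------------

    def partial_optimize(self, pos, free_atoms, active=None, tol=1e-4,
                         max_steps=800, extra_objective=None):
        """L-BFGS on the free atoms; frozen/inactive atoms never move.

        ``extra_objective(pos) -> (E, grad)`` lets callers add restraints
        (used by the constrained transfer-coordinate scan).  Returns
        (positions, OptimizeResult); max |gradient component| on free atoms
        is driven below ``tol`` (kcal/mol/Å).
        """
        pos = np.array(pos, dtype=float)
        free_atoms = np.asarray(sorted(free_atoms), dtype=int)
        if len(free_atoms) == 0:
            return pos, OptimizeResult(True, 0, self.energy(pos, active), 0.0,
                                       "nothing to optimize")

        def fun(x):
            p = pos.copy()
            p[free_atoms] = x.reshape(-1, 3)
            e, g = self.energy_gradient(p, active)
            if extra_objective is not None:
                e2, g2 = extra_objective(p)
                e += e2
                g = g + g2
            return e, g[free_atoms].ravel()

        res = minimize(fun, pos[free_atoms].ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": max_steps, "gtol": tol * 0.2,
                                "ftol": 1e-14})
        out = pos.copy()
        out[free_atoms] = res.x.reshape(-1, 3)
        _, g = fun(res.x)
        max_grad = float(np.max(np.abs(g))) if len(g) else 0.0
        converged = max_grad <= tol
        return out, OptimizeResult(converged, int(res.nit),
                                   float(res.fun), max_grad,
                                   "" if converged else "not converged; best so far")

    # -- Hessian / frequencies ------------------------------------------------

    def hessian(self, pos, free_atoms, active=None, masses=None, step=1e-3,
                grad_tol=1e-3):
        """Central-difference Hessian over the free atoms.

        Returns a :class:`HessianResult` with the mass-weighted matrix,
        harmonic frequencies (cycles / t.u.), ZPE over real modes (kcal/mol)
        and the count of imaginary modes.  Requesting this away from a
        stationary point attaches a warning instead of failing.
        """
        pos = np.array(pos, dtype=float)
        free_atoms = np.asarray(sorted(free_atoms), dtype=int)
        n = len(free_atoms)
        g0 = self.gradient(pos, active)[free_atoms]
        warning = None
        if np.max(np.abs(g0)) > grad_tol:
            warning = (f"Hessian requested at a non-stationary geometry "
                       f"(max |g| = {np.max(np.abs(g0)):.2e})")
            warnings.warn(warning)
        H = np.zeros((3 * n, 3 * n))
        for k in range(3 * n):
            a, c = divmod(k, 3)
            p = pos.copy()
            p[free_atoms[a], c] += step
            gp = self.gradient(p, active)[free_atoms].ravel()
            p[free_atoms[a], c] -= 2 * step
            gm = self.gradient(p, active)[free_atoms].ravel()
            H[:, k] = (gp - gm) / (2 * step)
        H = 0.5 * (H + H.T)
        if masses is None:
            raise ValueError("masses (per system atom) required for frequencies")
        m = np.repeat(np.asarray(masses)[free_atoms], 3)
        W = 1.0 / np.sqrt(m)
        Hmw = H * np.outer(W, W)
        evals, evecs = np.linalg.eigh(Hmw)
        n_imag = int(np.sum(evals < -ZERO_MODE_TOL))
        pos_evals = evals[evals > ZERO_MODE_TOL]
        freqs = np.sqrt(pos_evals) / (2.0 * np.pi)       # 1 / t.u.
        zpe = 0.5 * PLANCK_KCALMOL_TU * float(np.sum(freqs))
        return HessianResult(matrix=Hmw, eigenvalues=evals, eigenvectors=evecs,
                             frequencies=freqs, zpe=zpe, n_imaginary=n_imag,
                             free_atoms=free_atoms, warning=warning)


@dataclass
class HessianResult:
    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    frequencies: np.ndarray   # cycles per t.u., real modes only
    zpe: float                # kcal/mol
    n_imaginary: int
    free_atoms: np.ndarray
    warning: str | None = None
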