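"""Stationary-point analysis of the methyl-transfer step.

Reactant and product are minima (no imaginary frequencies) of the backend
surface; the transition state is the first-order saddle (exactly one
imaginary mode) between them, located by a constrained scan along the
transfer coordinate ξ = R(O–C) − R(S–C) (reactant ξ > 0, product ξ < 0)
followed by a Newton saddle polish on the full free-coordinate Hessian.

Reaction energetics are ZPE-corrected (real modes only; the imaginary mode
is excluded at the TS) and reported relative to each member's reactant,
then averaged over the ensemble with the sample standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backend import SurrogateBackend
from .partition import CappedCluster

_SCAN_K = 2000.0          # restraint stiffness for the ξ scan, kcal/mol/Å²


class NoBarrierError(RuntimeError):
    """The constrained scan found no interior maximum."""


@dataclass
class StationaryPoint:
    cluster: CappedCluster
    energy: float             # kcal/mol (electronic surrogate energy)
    zpe: float                # kcal/mol, over real modes
    n_imaginary: int
    kind: str                 # "reactant" | "ts" | "product" | "minimum"
    xi: float | None = None
    metrics: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def corrected_energy(self) -> float:
        return self.energy + self.zpe


def _transfer_atoms(backend: SurrogateBackend):
    tr = backend.params.transfer
    if tr is None:
        raise ValueError("backend has no methyl-transfer term")
    return tr


def _xi(pos, tr) -> float:
    return float(np.linalg.norm(pos[tr.o] - pos[tr.c])
                 - np.linalg.norm(pos[tr.s] - pos[tr.c]))


def _point_metrics(pos, backend: SurrogateBackend) -> dict:
    tr = backend.params.transfer
    pr = backend.params.proton
    out = {}
    if tr is not None:
        vo = pos[tr.o] - pos[tr.c]
        vs = pos[tr.s] - pos[tr.c]
        out["R(O-C)"] = float(np.linalg.norm(vo))
        out["R(S-C)"] = float(np.linalg.norm(vs))
        c = float(vo @ vs / (np.linalg.norm(vo) * np.linalg.norm(vs)))
        out["angle(O-C-S)"] = float(np.degrees(np.arccos(np.clip(c, -1, 1))))
    if pr is not None:
        out["R(O-H)"] = float(np.linalg.norm(pos[pr.h] - pos[pr.o]))
    return out


def _masses(backend: SurrogateBackend, system_masses) -> np.ndarray:
    return np.asarray(system_masses, dtype=float)


def _make_point(cluster, full, backend, masses, kind, free, active,
                grad_tol) -> StationaryPoint:
    hess = backend.hessian(full, free, active=active, masses=masses,
                           grad_tol=grad_tol)
    tr = backend.params.transfer
    xi = _xi(full, tr) if tr is not None else None
    pt = StationaryPoint(
        cluster=cluster.with_positions(full),
        energy=float(backend.energy(full, active)),
        zpe=hess.zpe, n_imaginary=hess.n_imaginary, kind=kind, xi=xi,
        metrics=_point_metrics(full, backend))
    if hess.warning:
        pt.flags.append(hess.warning)
    return pt, hess


def _side_restraint(backend, side: str, boundary: float, k: float = 100.0):
    """One-sided harmonic keeping ξ on one side of ``boundary`` during a
    relaxation.  If the restraint is inactive at the solution the result is
    an unrestrained stationary point; the guard only prevents line searches
    from hopping the barrier into the other basin."""
    tr = backend.params.transfer
    sign = 1.0 if side == "reactant" else -1.0

    def pen(pos):
        vo = pos[tr.o] - pos[tr.c]
        vs = pos[tr.s] - pos[tr.c]
        dOC = np.linalg.norm(vo)
        dSC = np.linalg.norm(vs)
        xi = dOC - dSC
        g = np.zeros_like(pos)
        excess = sign * (boundary - xi)
        if excess <= 0:
            return 0.0, g
        e = 0.5 * k * excess * excess
        dE_dxi = -sign * k * excess
        uo, us = vo / dOC, vs / dSC
        g[tr.o] += dE_dxi * uo
        g[tr.s] += -dE_dxi * us
        g[tr.c] += dE_dxi * (us - uo)
        return e, g
    return pen


def find_minimum(start: CappedCluster, backend: SurrogateBackend,
                 masses, frozen=None, tol: float = 1e-4,
                 side: str | None = None) -> StationaryPoint:
    """Relax to the nearest minimum and confirm it by frequency count.

    ``kind`` is assigned from the sign of ξ when a transfer term exists
    (positive: reactant side).  ``side`` ("reactant" | "product") adds a
    basin guard that is inactive at the solution.  Convergence onto a
    saddle is flagged, not silently accepted.
    """
    full, _ = start.full_positions()
    active = start.evaluation_mask()
    free = sorted(set(start.free_atoms) - set(frozen or ()))
    guard = None
    if side is not None and backend.params.transfer is not None:
        a = backend.params.transfer.xi_well
        guard = _side_restraint(backend, side,
                                0.3 * a if side == "reactant" else -0.3 * a)
    full, res = backend.partial_optimize(full, free, active=active, tol=tol,
                                         extra_objective=guard)
    tr = backend.params.transfer
    kind = "minimum"
    if tr is not None:
        kind = "reactant" if _xi(full, tr) > 0 else "product"
    pt, _h = _make_point(start, full, backend, masses, kind, free, active,
                         grad_tol=10 * tol)
    if not res.converged:
        pt.flags.append("optimizer did not reach tolerance")
    if pt.n_imaginary > 0:
        pt.flags.append(f"converged to a stationary point with "
                        f"{pt.n_imaginary} imaginary modes (saddle)")
    return pt


def _scan(start_full, backend, free, active, xi_values, tol=2e-4):
    """Restrained minimization at each ξ target; returns geometries and the
    unrestrained energies along the path."""
    tr = backend.params.transfer
    path, energies = [], []
    full = np.array(start_full)
    for target in xi_values:
        def restraint(pos, target=target):
            vo = pos[tr.o] - pos[tr.c]
            vs = pos[tr.s] - pos[tr.c]
            dOC = np.linalg.norm(vo)
            dSC = np.linalg.norm(vs)
            xi = dOC - dSC
            e = 0.5 * _SCAN_K * (xi - target) ** 2
            dE = _SCAN_K * (xi - target)
            g = np.zeros_like(pos)
            uo, us = vo / dOC, vs / dSC
            g[tr.o] += dE * uo
            g[tr.s] += -dE * us
            g[tr.c] += dE * (us - uo)
            return e, g
        full, _res = backend.partial_optimize(full, free, active=active,
                                              tol=tol,
                                              extra_objective=restraint)
        path.append(full.copy())
        energies.append(float(backend.energy(full, active)))
    return path, np.array(energies)


def _newton_polish(full, backend, free, active, masses, tol=1e-6,
                   max_iter=80, max_step=0.2):
    free = np.asarray(sorted(free), dtype=int)
    x = np.array(full)
    for _ in range(max_iter):
        g = backend.gradient(x, active)[free].ravel()
        if np.max(np.abs(g)) < tol:
            return x, True
        hess = backend.hessian(x, free, active=active, masses=masses,
                               grad_tol=np.inf)
        # Cartesian (non-mass-weighted) Hessian for the Newton step
        m = np.repeat(np.asarray(masses)[free], 3)
        H = hess.matrix * np.outer(np.sqrt(m), np.sqrt(m))
        evals, evecs = np.linalg.eigh(H)
        keep = np.abs(evals) > 1e-6
        coeff = evecs.T @ g
        step = -(evecs[:, keep] @ (coeff[keep] / evals[keep]))
        norm = np.max(np.abs(step))
        if norm > max_step:
            step *= max_step / norm
        x[free] += step.reshape(-1, 3)
    g = backend.gradient(x, active)[free].ravel()
    return x, bool(np.max(np.abs(g)) < tol * 10)


def find_ts(reactant: StationaryPoint, product: StationaryPoint,
            backend: SurrogateBackend, masses, frozen=None,
            n_scan: int = 41) -> StationaryPoint:
    """Locate the saddle between two minima on the transfer coordinate.

    A constrained scan over ξ (relaxing all other free coordinates) brackets
    the barrier; the highest interior point is polished by a Newton saddle
    search on the full free-space Hessian.  The result must carry exactly
    one imaginary mode whose eigenvector is dominated by the transferring
    group; a failed polish returns the scan maximum flagged "unpolished".
    """
    tr = _transfer_atoms(backend)
    if not (reactant.xi is not None and product.xi is not None
            and reactant.xi > product.xi):
        raise ValueError("expected reactant.ξ > product.ξ (transfer S→O)")
    cluster = reactant.cluster
    active = cluster.evaluation_mask()
    free = sorted(set(cluster.free_atoms) - set(frozen or ()))
    full, _ = cluster.full_positions()
    xi_values = np.linspace(reactant.xi, product.xi, n_scan)
    path, energies = _scan(full, backend, free, active, xi_values)
    k_max = int(np.argmax(energies))
    if k_max in (0, len(energies) - 1):
        raise NoBarrierError("no barrier on path: scan maximum at an endpoint")
    polished, ok = _newton_polish(path[k_max], backend, free, active, masses)
    flags = []
    if ok:
        geom = polished
    else:
        geom = path[k_max]
        flags.append("unpolished")
    pt, hess = _make_point(cluster, geom, backend, masses, "ts", free, active,
                           grad_tol=1e-3 if ok else np.inf)
    pt.flags.extend(flags)
    if pt.n_imaginary != 1:
        pt.flags.append(f"{pt.n_imaginary} imaginary modes at the TS")
    else:
        # the imaginary eigenvector should live on the transferring group
        vec = hess.eigenvectors[:, 0]
        free_arr = np.asarray(sorted(free))
        weights = vec.reshape(-1, 3)
        w = np.linalg.norm(weights, axis=1)
        top = free_arr[int(np.argmax(w))]
        if top not in (tr.c, tr.o, tr.s) and (backend.params.proton is None or
                                              top != backend.params.proton.h):
            pt.flags.append("imaginary mode not centered on the transfer group")
    return pt


def transfer_path(start: CappedCluster, backend: SurrogateBackend, masses,
                  frozen=None, n_scan: int = 41):
    """Reactant, TS and product reached from one starting cluster.

    The product is whatever downhill relaxation finds from the scan's last
    point (the product-side basin nearest the path).
    """
    tr = _transfer_atoms(backend)
    reactant = find_minimum(start, backend, masses, frozen=frozen)
    active = start.evaluation_mask()
    free = sorted(set(start.free_atoms) - set(frozen or ()))
    full, _ = reactant.cluster.full_positions()
    xi_values = np.linspace(reactant.xi, -tr.xi_well, n_scan)
    path, _energies = _scan(full, backend, free, active, xi_values)
    product = find_minimum(reactant.cluster.with_positions(path[-1]),
                           backend, masses, frozen=frozen, side="product")
    ts = find_ts(reactant, product, backend, masses, frozen=frozen,
                 n_scan=n_scan)
    return reactant, ts, product


# ---------------------------------------------------------------------------
# ensemble profiles


@dataclass
class ReactionProfile:
    members: list               # per-member dict of energies and metrics
    n_failed: int
    table: pd.DataFrame         # mean (sd) rows in the conventional layout

    def mean(self, key: str) -> float:
        return float(np.mean([m[key] for m in self.members]))

    def sd(self, key: str) -> float:
        vals = [m[key] for m in self.members]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def reaction_profile(ensemble, backend: SurrogateBackend, masses,
                     frozen=None, n_scan: int = 41) -> ReactionProfile:
    """ZPE-corrected, ensemble-averaged reaction profile.

    ``ensemble`` is a list of reactant-side CappedClusters.  Members whose
    TS search fails are excluded and counted, never silently dropped.
    """
    ensemble = list(ensemble)
    if len(ensemble) < 2:
        raise ValueError("need at least 2 ensemble members")
    members, n_failed = [], 0
    for k, start in enumerate(ensemble):
        try:
            reactant, ts, product = transfer_path(start, backend, masses,
                                                  frozen=frozen, n_scan=n_scan)
        except (NoBarrierError, ValueError) as e:
            warnings.warn(f"ensemble member {k}: TS search failed ({e})")
            n_failed += 1
            continue
        members.append({
            "dE_ts": ts.corrected_energy - reactant.corrected_energy,
            "dE_rxn": product.corrected_energy - reactant.corrected_energy,
            "R(O-H) React": reactant.metrics.get("R(O-H)", np.nan),
            "R(O-H) TS": ts.metrics.get("R(O-H)", np.nan),
            "R(O-H) Prod": product.metrics.get("R(O-H)", np.nan),
            "R(O-C) TS": ts.metrics["R(O-C)"],
            "R(S-C) TS": ts.metrics["R(S-C)"],
            "points": (reactant, ts, product),
        })
    if not members:
        raise RuntimeError("every ensemble member failed the TS search")

    def stat(key):
        vals = np.array([m[key] for m in members])
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        return f"{vals.mean():.2f} ({sd:.2f})"

    table = pd.DataFrame([{
        "Energy TS": stat("dE_ts"),
        "Energy Prod.": stat("dE_rxn"),
        "R(O-H) React.": stat("R(O-H) React"),
        "R(O-H) TS": stat("R(O-H) TS"),
        "R(O-H) Prod.": stat("R(O-H) Prod"),
        "R(O-C) TS": stat("R(O-C) TS"),
        "R(S-C) TS": stat("R(S-C) TS"),
        "n": len(members),
        "excluded": n_failed,
    }])
    return ReactionProfile(members=members, n_failed=n_failed, table=table)


def base_proton_track(points) -> dict:
    """R(O–H_base) across stationary points, with a monotonicity flag.

    Returns {"values": {kind: Å or None}, "monotone": bool | None}; the
    metric is reported as absent (None) when no base proton exists.
    """
    values = {}
    for pt in points:
        values[pt.kind] = pt.metrics.get("R(O-H)")
    if any(v is None for v in values.values()) or not values:
        return {"values": values, "monotone": None}
    order = [k for k in ("reactant", "ts", "product") if k in values]
    seq = [values[k] for k in order]
    monotone = all(a <= b + 1e-9 for a, b in zip(seq, seq[1:]))
    return {"values": values, "monotone": monotone}
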