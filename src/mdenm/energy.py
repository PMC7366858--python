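"""Coarse-grained potential energy, forces, group interaction energies
and staged minimization.

Functional forms
----------------
bonds / native contacts   E = ½ k (r - r0)²
angles                    E = ½ k (θ - θ0)²
vdW (non-native pairs)    E = ε_ij [(r_min/r)¹² - 2 (r_min/r)⁶],
                          ε_ij = √(ε_i ε_j), r_min = r_i + r_j
electrostatics            E = 332.0637 q_i q_j exp(-r/λ) / (ε_r r)

Both pair terms are tapered to zero by a CHARMM-style switching
function between ``switch_on`` and ``cutoff`` (defaults 10-12 Å).
Pairs joined by a bond, an angle (1-3) or a native contact are
excluded from the nonbonded sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from . import _kernels
from .constants import COULOMB_K
from .model import Conformation, Topology

logger = logging.getLogger(__name__)


class MinimizationError(RuntimeError):
    pass


class OverlapError(ValueError):
    """Two beads sit below the hard-core distance."""


@dataclass
class EnergyBreakdown:
    bond: float
    angle: float
    native_contact: float
    vdw: float
    electrostatic: float
    total: float

    @classmethod
    def from_components(cls, bond, angle, native_contact, vdw, electrostatic):
        return cls(bond=bond, angle=angle, native_contact=native_contact,
                   vdw=vdw, electrostatic=electrostatic,
                   total=bond + angle + native_contact + vdw + electrostatic)


class PackedForceField:
    """Topology flattened into the array layout the kernels expect."""

    def __init__(self, topo: Topology):
        n = topo.n_beads
        self.n = n
        self.masses = np.ascontiguousarray(topo.masses, dtype=np.float64)
        self.charges = np.ascontiguousarray(topo.charges, dtype=np.float64)
        self.b_i = np.ascontiguousarray(topo.bonds[:, 0], dtype=np.int64)
        self.b_j = np.ascontiguousarray(topo.bonds[:, 1], dtype=np.int64)
        self.b_k = np.ascontiguousarray(topo.bond_k, dtype=np.float64)
        self.b_r0 = np.ascontiguousarray(topo.bond_r0, dtype=np.float64)
        self.a_i = np.ascontiguousarray(topo.angles[:, 0], dtype=np.int64)
        self.a_j = np.ascontiguousarray(topo.angles[:, 1], dtype=np.int64)
        self.a_k = np.ascontiguousarray(topo.angles[:, 2], dtype=np.int64)
        self.a_kf = np.ascontiguousarray(topo.angle_k, dtype=np.float64)
        self.a_t0 = np.ascontiguousarray(topo.angle_t0, dtype=np.float64)
        self.c_i = np.ascontiguousarray(topo.native_contacts[:, 0], dtype=np.int64)
        self.c_j = np.ascontiguousarray(topo.native_contacts[:, 1], dtype=np.int64)
        self.c_k = np.ascontiguousarray(topo.contact_k, dtype=np.float64)
        self.c_r0 = np.ascontiguousarray(topo.contact_r0, dtype=np.float64)
        self.eps = np.ascontiguousarray(topo.lj_eps, dtype=np.float64)
        self.rmin_half = np.ascontiguousarray(topo.lj_rmin_half, dtype=np.float64)
        nb = topo.nonbonded
        self.dielectric = float(nb.dielectric)
        self.lam_inv = 1.0 / float(nb.debye_length)
        self.r_on = float(nb.switch_on)
        self.r_cut = float(nb.cutoff)
        self.hardcore = float(nb.hardcore)
        excl = np.zeros((n, n), dtype=np.uint8)
        for i, j in topo.bonds:
            excl[i, j] = excl[j, i] = 1
        for i, _, k in topo.angles:
            excl[i, k] = excl[k, i] = 1
        for i, j in topo.native_contacts:
            excl[i, j] = excl[j, i] = 1
        np.fill_diagonal(excl, 1)
        self.excl = excl

    def kernel_args(self):
        return (self.charges, self.excl,
                self.b_i, self.b_j, self.b_k, self.b_r0,
                self.a_i, self.a_j, self.a_k, self.a_kf, self.a_t0,
                self.c_i, self.c_j, self.c_k, self.c_r0,
                self.eps, self.rmin_half,
                self.dielectric, self.lam_inv, self.r_on, self.r_cut)


def packed(topo: Topology) -> PackedForceField:
    """Memoised packed view of a topology."""
    ff = getattr(topo, "_packed", None)
    if ff is None:
        ff = PackedForceField(topo)
        object.__setattr__(topo, "_packed", ff)
    return ff


def _check_hardcore(ff: PackedForceField, x: np.ndarray) -> None:
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    mask = (ff.excl == 0) & (d < ff.hardcore)
    if np.any(mask):
        i, j = np.argwhere(mask)[0]
        raise OverlapError(
            f"beads {int(i)} and {int(j)} overlap at {d[i, j]:.3f} Å "
            f"(< hard core {ff.hardcore} Å)")


def raw_forces(ff: PackedForceField, x: np.ndarray
               ) -> Tuple[np.ndarray, Tuple[float, float, float, float, float]]:
    F = np.empty_like(x)
    comps = _kernels.compute_forces(np.ascontiguousarray(x, dtype=np.float64),
                                    *ff.kernel_args(), F)
    return F, comps


def energy_forces(topology: Topology, conf: Conformation
                  ) -> Tuple[EnergyBreakdown, np.ndarray]:
    """Potential energy breakdown and analytic forces (kcal/mol, kcal/mol/Å)."""
    x = np.asarray(conf.coordinates, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("coordinates contain non-finite values")
    ff = packed(topology)
    _check_hardcore(ff, x)
    F, comps = raw_forces(ff, x)
    return EnergyBreakdown.from_components(*comps), F


def group_interaction_energy(topology: Topology, conf: Conformation,
                             group_a: np.ndarray, group_b: np.ndarray
                             ) -> Tuple[float, float, float]:
    """Cross-group nonbonded interaction energy (electrostatic, vdW, total).

    Only pairs with one bead in each group contribute; excluded
    (bonded / 1-3 / native-contact) pairs are skipped, matching the
    full potential.  Symmetric in the two groups.
    """
    a_idx = _as_index(group_a, topology.n_beads)
    b_idx = _as_index(group_b, topology.n_beads)
    if np.intersect1d(a_idx, b_idx).size:
        raise ValueError("groups overlap")
    ff = packed(topology)
    x = np.asarray(conf.coordinates, dtype=np.float64)
    dv = x[a_idx][:, None, :] - x[b_idx][None, :, :]
    r = np.sqrt(np.sum(dv * dv, axis=-1))
    keep = (ff.excl[np.ix_(a_idx, b_idx)] == 0) & (r < ff.r_cut)
    if not np.any(keep):
        return 0.0, 0.0, 0.0
    r = r[keep]
    eps_ij = np.sqrt(np.outer(ff.eps[a_idx], ff.eps[b_idx]))[keep]
    rm = np.add.outer(ff.rmin_half[a_idx], ff.rmin_half[b_idx])[keep]
    qq = np.outer(ff.charges[a_idx], ff.charges[b_idx])[keep]
    sr6 = (rm / r) ** 6
    v_lj = eps_ij * (sr6 * sr6 - 2.0 * sr6)
    v_el = COULOMB_K * qq * np.exp(-r * ff.lam_inv) / (ff.dielectric * r)
    rc2, ron2 = ff.r_cut ** 2, ff.r_on ** 2
    r2 = r * r
    sw = np.where(
        r2 > ron2,
        (rc2 - r2) ** 2 * (rc2 + 2.0 * r2 - 3.0 * ron2) / (rc2 - ron2) ** 3,
        1.0)
    elec = float(np.sum(sw * v_el))
    vdw = float(np.sum(sw * v_lj))
    return elec, vdw, elec + vdw


def _as_index(group, n: int) -> np.ndarray:
    g = np.asarray(group)
    if g.dtype == bool:
        if g.shape != (n,):
            raise ValueError("boolean group mask has wrong length")
        return np.nonzero(g)[0]
    return g.astype(int)


@dataclass
class MinimizeSettings:
    force_tol: float = 1e-4       # kcal/mol/Å, max |component|
    sd_steps: int = 200
    max_iterations: int = 50000
    sd_step_size: float = 1e-3    # initial steepest-descent step, Å
    #: positional-restraint force constants (kcal/mol/Å²) applied in
    #: decreasing stages before the unrestrained stage; keeps the
    #: soft, detached tail in its own basin instead of letting the
    #: line search walk it across flat directions onto the domain
    restraint_schedule: Tuple[float, ...] = ()


def minimize(topology: Topology, conf: Conformation,
             settings: Optional[MinimizeSettings] = None) -> Conformation:
    """Staged minimization: optional restrained stages, steepest descent,
    then L-BFGS refinement.

    Converges when every force component is below ``force_tol`` or the
    iteration budget is exhausted; the energy is non-increasing across
    accepted steps.
    """
    settings = settings or MinimizeSettings()
    ff = packed(topology)
    x = np.array(conf.coordinates, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("non-finite starting coordinates")

    def eval_at(xf):
        F, comps = raw_forces(ff, xf.reshape(-1, 3))
        return float(sum(comps)), -F.ravel()

    x0 = x.ravel().copy()
    for k_r in settings.restraint_schedule:
        def eval_restrained(xf, k_r=k_r):
            e, g = eval_at(xf)
            dx = xf - x0
            return e + 0.5 * k_r * float(dx @ dx), g + k_r * dx

        res = _scipy_minimize(eval_restrained, x.ravel(), jac=True,
                              method="L-BFGS-B",
                              options={"maxiter": 2000, "ftol": 1e-14,
                                       "gtol": 1e-4})
        x = res.x.reshape(-1, 3)

    e, g = eval_at(x.ravel())
    if not np.isfinite(e):
        raise MinimizationError("non-finite starting energy")
    if np.max(np.abs(g)) < settings.force_tol:
        return Conformation(x, provenance=conf.provenance + " | minimized (already)",
                            residue_index=conf.residue_index)

    # steepest descent with backtracking
    step = settings.sd_step_size
    xf = x.ravel()
    for _ in range(settings.sd_steps):
        gmax = np.max(np.abs(g))
        if gmax < settings.force_tol:
            break
        trial = xf - step * g / max(gmax, 1.0)
        e_t, g_t = eval_at(trial)
        if e_t < e:
            xf, e, g = trial, e_t, g_t
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-12:
                raise MinimizationError("steepest descent cannot reduce the energy")

    # quasi-Newton refinement, repeated until the force tolerance holds
    budget = settings.max_iterations
    for _ in range(6):
        if np.max(np.abs(g)) < settings.force_tol or budget <= 0:
            break
        res = _scipy_minimize(eval_at, xf, jac=True, method="L-BFGS-B",
                              options={"maxiter": budget, "ftol": 1e-16,
                                       "gtol": 0.25 * settings.force_tol,
                                       "maxcor": 30})
        budget -= res.nit
        if res.fun > e + 1e-6:
            raise MinimizationError("energy increased beyond line-search recovery")
        xf, e = res.x, float(res.fun)
        _, g = eval_at(xf)
    gmax = float(np.max(np.abs(g)))
    if gmax > settings.force_tol:
        logger.warning("minimization budget exhausted at max|F| = %.3e", gmax)
    return Conformation(xf.reshape(-1, 3),
                        provenance=conf.provenance + " | minimized",
                        residue_index=conf.residue_index)
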