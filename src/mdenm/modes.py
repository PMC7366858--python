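"""Mass-weighted Hessian, vibrational modes, and excitation-mode selection.

The Hessian is built by central finite differences of the analytic
forces; the mass-weighted matrix M^{-1/2} H M^{-1/2} is diagonalised
with ``scipy.linalg.eigh``.  Rigid-body modes are identified by an
eigenvalue tolerance (a single connected nonlinear molecule has six,
a linear one five); the lowest-frequency internal modes are retained
for excitation, together with their Cartesian displacement fields
normalised so that displacing the reference by s Å along a field
produces an all-bead RMSD of exactly s Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg

from . import energy as _energy
from .constants import eigenvalue_to_wavenumber
from .model import Conformation, Topology


class NotMinimizedError(RuntimeError):
    pass


@dataclass
class ModeSet:
    """Selected internal vibrational modes of a minimized structure."""

    eigenvalues: np.ndarray        # internal units, selected modes, ascending
    frequencies_cm: np.ndarray     # cm^-1, same order
    eigenvectors_mw: np.ndarray    # (3N, n_selected), mass-weighted, orthonormal
    cartesian_shapes: np.ndarray   # (n_selected, N, 3), RMSD-1 normalised
    n_zero_modes: int
    reference: Conformation
    masses: np.ndarray
    #: per-mode, per-bead displacement magnitude of the RMSD-1 field
    #: (the mode's relative RMSF contribution, for ranking/reporting)
    bead_amplitudes: np.ndarray    # (n_selected, N)
    #: full spectrum, for reconstruction / projection diagnostics
    full_eigenvalues: np.ndarray
    full_eigenvectors_mw: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    @property
    def n_beads(self) -> int:
        return self.masses.size

    def project_mw(self, cartesian_field: np.ndarray) -> np.ndarray:
        """Coefficients of a Cartesian field in the selected mass-weighted basis."""
        mw = (cartesian_field * np.sqrt(self.masses)[:, None]).ravel()
        return self.eigenvectors_mw.T @ mw


def compute_hessian(topology: Topology, minimized: Conformation,
                    h: float = 1e-4, symmetrize: bool = True,
                    force_tol: float = 1e-4) -> np.ndarray:
    """3N×3N Hessian (kcal/mol/Å²) by central differences of the forces."""
    ff = _energy.packed(topology)
    x = np.asarray(minimized.coordinates, dtype=np.float64)
    F, _ = _energy.raw_forces(ff, x)
    gmax = float(np.max(np.abs(F)))
    if gmax > 10.0 * force_tol:
        raise NotMinimizedError(
            f"structure is not minimized (max |force| = {gmax:.3e} kcal/mol/Å)")
    n3 = x.size
    H = np.empty((n3, n3))
    flat = x.ravel().copy()
    for j in range(n3):
        orig = flat[j]
        flat[j] = orig + h
        Fp, _ = _energy.raw_forces(ff, flat.reshape(-1, 3))
        flat[j] = orig - h
        Fm, _ = _energy.raw_forces(ff, flat.reshape(-1, 3))
        flat[j] = orig
        H[:, j] = -(Fp - Fm).ravel() / (2.0 * h)
    if symmetrize:
        H = 0.5 * (H + H.T)
    return H


def _rigid_body_basis(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted rigid-body vectors (3 translations plus
    the independent rotations; rank 5 for a linear molecule)."""
    n = masses.size
    sq = np.sqrt(masses)
    fields = []
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = 1.0
        fields.append(v)
    com = np.average(coords, weights=masses, axis=0)
    rel = coords - com
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        fields.append(np.cross(e, rel))
    V = np.stack([(v * sq[:, None]).ravel() for v in fields], axis=1)
    U, s, _ = np.linalg.svd(V, full_matrices=False)
    return U[:, s > 1e-8 * s[0]]


def compute_modes(hessian: np.ndarray, topology: Topology,
                  n_select: int = 10, zero_tol: float = 1e-6,
                  reference: Optional[Conformation] = None) -> ModeSet:
    """Diagonalise the mass-weighted Hessian and keep the lowest internal modes.

    With a ``reference`` structure the rigid-body subspace is projected
    out before diagonalisation (the floppy tail has genuine internal
    modes softer than any practical eigenvalue threshold); without one,
    modes below ``zero_tol`` are discarded as rigid-body motion.
    """
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    masses = np.asarray(topology.masses, dtype=np.float64)
    m3 = np.repeat(masses, 3)
    inv_sqrt_m = 1.0 / np.sqrt(m3)
    Hmw = hessian * np.outer(inv_sqrt_m, inv_sqrt_m)
    Hmw = 0.5 * (Hmw + Hmw.T)
    if reference is not None:
        B = _rigid_body_basis(np.asarray(reference.coordinates), masses)
        HB = Hmw @ B
        Hmw = Hmw - HB @ B.T - B @ HB.T + B @ (B.T @ HB) @ B.T
        Hmw = 0.5 * (Hmw + Hmw.T)
        n_zero = B.shape[1]
    else:
        n_zero = -1  # determined by threshold below
    evals, evecs = scipy.linalg.eigh(Hmw)
    if n_zero < 0:
        zero = np.abs(evals) < zero_tol
        n_zero = int(np.count_nonzero(zero))
        internal = np.nonzero(~zero)[0]
    else:
        internal = np.arange(n_zero, evals.size)
    if internal.size and evals[internal[0]] < -zero_tol:
        raise ValueError(
            f"negative internal eigenvalue {evals[internal[0]]:.3e}: "
            "structure is not a minimum")
    if internal.size < n_select:
        raise ValueError(
            f"only {internal.size} internal modes available, {n_select} requested")
    sel = internal[:n_select]
    sel_vecs = evecs[:, sel]
    n = masses.size
    cart = (sel_vecs * inv_sqrt_m[:, None]).T.reshape(n_select, n, 3)
    # normalise each field so a 1 Å displacement gives an all-bead RMSD of 1 Å
    norms = np.sqrt(np.sum(cart ** 2, axis=(1, 2)) / n)
    cart = cart / norms[:, None, None]
    amplitudes = np.sqrt(np.sum(cart ** 2, axis=2)) / np.sqrt(n)
    return ModeSet(
        eigenvalues=evals[sel].copy(),
        frequencies_cm=np.array([eigenvalue_to_wavenumber(ev) for ev in evals[sel]]),
        eigenvectors_mw=sel_vecs.copy(),
        cartesian_shapes=cart,
        n_zero_modes=n_zero,
        reference=reference if reference is not None else Conformation(
            np.zeros((n, 3))),
        masses=masses,
        bead_amplitudes=amplitudes,
        full_eigenvalues=evals,
        full_eigenvectors_mw=evecs,
    )


def export_modes(modeset: ModeSet, path) -> None:
    """Write the selected mass-weighted eigenvectors as a plain-text matrix
    (one mode per column, header row of frequencies in cm^-1)."""
    header = " ".join(f"{f:.6f}" for f in modeset.frequencies_cm)
    np.savetxt(path, modeset.eigenvectors_mw, header=f"freq_cm {header}")
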