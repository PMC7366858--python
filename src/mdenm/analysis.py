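"""Ensemble statistics: contact population maps, HVR binding-state
classification, interaction-energy distributions relative to a
detached-HVR reference, nucleotide–switch energetics, RMSF, RMSD and
Cα pseudo-dihedral profiles.

The HVR interaction-energy statistic is the difference between a bound
conformation's HVR–environment interaction energy and the mean over
the detached-HVR reference group:

    ΔE_HVR(a/e) = E_bound(a/e) − ⟨E_non-bound⟩

computed as a sum of pairwise electrostatic and vdW contributions
between the HVR (tail residues plus the farnesyl bead) and the rest of
the system (protein, nucleotide, Mg²⁺).  With an implicit solvent
there is no explicit solvent term in the environment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .energy import group_interaction_energy
from .engine import EnsembleRecord
from .model import Conformation, GLY60, Topology

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# superposition

@dataclass
class Transform:
    rotation: np.ndarray      # (3, 3)
    translation: np.ndarray   # (3,) applied after rotation about centroids
    mobile_centroid: np.ndarray
    reference_centroid: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.mobile_centroid) @ self.rotation.T \
            + self.reference_centroid


def superpose_rmsd(mobile: Conformation, reference: Conformation,
                   selection: Optional[np.ndarray] = None
                   ) -> Tuple[Transform, float]:
    """Optimal least-squares (Kabsch) superposition over a selection.

    Returns the rigid transform and the post-fit RMSD over the
    selection.  A degenerate selection (< 3 non-collinear points)
    falls back to translation-only with a warning.
    """
    xm = np.asarray(mobile.coordinates, dtype=float)
    xr = np.asarray(reference.coordinates, dtype=float)
    if selection is None:
        sel_m = xm
        sel_r = xr
    else:
        sel = np.asarray(selection)
        idx = np.nonzero(sel)[0] if sel.dtype == bool else sel.astype(int)
        if idx.size == 0:
            raise ValueError("empty selection")
        sel_m = xm[idx]
        sel_r = xr[idx]
    if sel_m.shape != sel_r.shape:
        raise ValueError("selection size differs between structures")
    cm = sel_m.mean(axis=0)
    cr = sel_r.mean(axis=0)
    a = sel_m - cm
    b = sel_r - cr
    rank = np.linalg.matrix_rank(a, tol=1e-8) if a.shape[0] >= 3 else 0
    if a.shape[0] < 3 or rank < 2:
        logger.warning("degenerate selection: translation-only superposition")
        R = np.eye(3)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # align_vectors warns on rank-2 sets
            rot, _ = Rotation.align_vectors(b, a)
        R = rot.as_matrix()
    fitted = a @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))
    tr = Transform(rotation=R, translation=cr - cm,
                   mobile_centroid=cm, reference_centroid=cr)
    return tr, rmsd


# ---------------------------------------------------------------------------
# contacts

@dataclass
class ContactMap:
    counts: np.ndarray        # (n_domain_res, n_hvr_res) population counts
    domain_residues: np.ndarray
    hvr_residues: np.ndarray
    n_conformations: int
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of the nonzero cells."""
        i, j = np.nonzero(self.counts)
        return pd.DataFrame({
            "domain_res": self.domain_residues[i],
            "hvr_res": self.hvr_residues[j],
            "count": self.counts[i, j],
        })


def _contact_geometry(topology: Topology):
    dom_idx = np.nonzero(topology.domain_mask)[0]
    hvr_idx = np.nonzero(topology.hvr_mask)[0]
    dom_res = topology.residue_index[dom_idx]
    hvr_res = topology.residue_index[hvr_idx]
    sep_ok = (np.abs(dom_res[:, None] - hvr_res[None, :])
              >= topology.contact_min_seq_sep)
    return dom_idx, hvr_idx, dom_res, hvr_res, sep_ok


def _pair_contacts(topology: Topology, coords: np.ndarray, cutoff: float
                   ) -> np.ndarray:
    """Boolean (domain residue × HVR residue) contact matrix, strict <."""
    dom_idx, hvr_idx, _, _, sep_ok = _contact_geometry(topology)
    d = np.linalg.norm(coords[dom_idx][:, None, :] - coords[hvr_idx][None, :, :],
                       axis=-1)
    return (d < cutoff) & sep_ok


def contact_map(ensemble: EnsembleRecord, topology: Topology,
                cutoff: float = 8.0) -> ContactMap:
    """Population counts of domain-residue / HVR-residue contacts.

    A residue pair is counted once per conformation when any inter-bead
    distance is strictly below the cutoff; sequence-adjacent pairs
    (|Δres| < ``topology.contact_min_seq_sep``) are not counted, since
    the covalent anchor region is always within any sensible cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    _, _, dom_res, hvr_res, _ = _contact_geometry(topology)
    counts = np.zeros((dom_res.size, hvr_res.size), dtype=int)
    for coords in ensemble.coordinates:
        counts += _pair_contacts(topology, coords, cutoff)
    return ContactMap(counts=counts, domain_residues=dom_res,
                      hvr_residues=hvr_res,
                      n_conformations=ensemble.n_conformations, cutoff=cutoff)


def classify_hvr_binding(conf: Conformation, topology: Topology,
                         cutoff: float = 8.0) -> str:
    """'detached' (no contacts), else the lobe with more HVR contacts;
    ties go to the lobe with the smaller minimum HVR distance."""
    contacts = _pair_contacts(topology, np.asarray(conf.coordinates), cutoff)
    if not contacts.any():
        return "detached"
    dom_idx, hvr_idx, dom_res, _, _ = _contact_geometry(topology)
    eff = topology.region["effector_lobe"][dom_idx]
    n_eff = int(contacts[eff].sum())
    n_allo = int(contacts[~eff].sum())
    if n_eff != n_allo:
        return "effector" if n_eff > n_allo else "allosteric"
    coords = np.asarray(conf.coordinates)
    d = np.linalg.norm(coords[dom_idx][:, None, :] - coords[hvr_idx][None, :, :],
                       axis=-1)
    return "effector" if d[eff].min() <= d[~eff].min() else "allosteric"


# ---------------------------------------------------------------------------
# interaction-energy distributions

@dataclass
class EnergyDistribution:
    values: np.ndarray          # ΔE_HVR per conformation, kcal/mol
    bound_energies: np.ndarray  # E_bound per conformation, kcal/mol
    group: str
    reference_mean: float
    reference_n: int

    @property
    def n(self) -> int:
        return self.values.size

    def summary(self) -> Dict[str, float]:
        if self.values.size == 0:
            return {"n": 0}
        hist, edges = np.histogram(self.values, bins=min(50, max(5, self.n // 5)))
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        return {"n": int(self.n), "mean": float(self.values.mean()),
                "min": float(self.values.min()), "mode": float(mode)}


def hvr_environment_energy(topology: Topology, conf: Conformation) -> float:
    """HVR(+farnesyl) vs. rest-of-system nonbonded interaction energy."""
    tail = topology.mask("hvr", "farnesyl")
    _, _, total = group_interaction_energy(topology, conf, tail, ~tail)
    return total


def hvr_interaction_energies(ensemble: EnsembleRecord, topology: Topology,
                             cutoff: float = 8.0, min_reference: int = 100
                             ) -> Dict[str, EnergyDistribution]:
    """ΔE_HVR distributions for the effector- and allosteric-bound groups.

    The reference ⟨E_non-bound⟩ is the mean HVR–environment energy over
    all detached conformations in the ensemble.  The detached group's
    own ΔE distribution (mean exactly zero) is included for reference.
    """
    labels = np.array([
        classify_hvr_binding(Conformation(c), topology, cutoff)
        for c in ensemble.coordinates])
    energies = np.array([
        hvr_environment_energy(topology, Conformation(c))
        for c in ensemble.coordinates])
    detached = labels == "detached"
    n_ref = int(detached.sum())
    if n_ref == 0:
        raise ValueError(
            "no detached conformations to define the reference state; "
            "enlarge the campaign")
    if n_ref < min_reference:
        logger.warning("detached reference group has only %d conformations "
                       "(recommended >= %d)", n_ref, min_reference)
    ref_mean = float(energies[detached].mean())
    out: Dict[str, EnergyDistribution] = {}
    for group in ("effector", "allosteric", "detached"):
        sel = labels == group
        out[group] = EnergyDistribution(
            values=energies[sel] - ref_mean,
            bound_energies=energies[sel],
            group=group, reference_mean=ref_mean, reference_n=n_ref)
    return out


@dataclass
class SwitchEnergetics:
    electrostatic: np.ndarray
    vdw: np.ndarray
    total: np.ndarray
    switch: str
    state_labels: Optional[np.ndarray] = None  # 1 / 2 per conformation (GTP)

    def summary(self) -> Dict[str, float]:
        s = {"n": int(self.total.size),
             "mean": float(self.total.mean()),
             "sd": float(self.total.std(ddof=1)) if self.total.size > 1 else 0.0}
        if self.state_labels is not None:
            s["state2_fraction"] = float(np.mean(self.state_labels == 2))
        return s


def nucleotide_switch_energies(ensemble: EnsembleRecord, topology: Topology,
                               switch: str = "II",
                               hbond_threshold: float = 4.5,
                               label_states: Optional[bool] = None
                               ) -> SwitchEnergetics:
    """Nucleotide(+Mg)–switch interaction energies per conformation.

    For GTP systems each conformation is also labelled state 2 when the
    γ-phosphate bead sits within ``hbond_threshold`` of the Gly60 bead
    (the H-bond proxy; the shorter distance is state 2), else state 1.
    """
    if switch not in ("I", "II"):
        raise ValueError("switch must be 'I' or 'II'")
    region = "switch1" if switch == "I" else "switch2"
    nuc = topology.mask("nucleotide", "magnesium")
    sw = topology.region[region]
    if not sw.any():
        raise ValueError(f"topology lacks {region} labels")
    if label_states is None:
        label_states = topology.state_tag == "GTP"
    if label_states and topology.state_tag != "GTP":
        raise ValueError("state-1/state-2 labels require the γ-phosphate bead")
    elec, vdw, tot = [], [], []
    for c in ensemble.coordinates:
        e, v, t = group_interaction_energy(topology, Conformation(c), nuc, sw)
        elec.append(e)
        vdw.append(v)
        tot.append(t)
    labels = None
    if label_states:
        gamma_idx = int(np.nonzero(topology.region["nucleotide"])[0][-1])
        g60_idx = topology.bead_of_residue(GLY60)
        d = np.linalg.norm(ensemble.coordinates[:, gamma_idx, :]
                           - ensemble.coordinates[:, g60_idx, :], axis=1)
        labels = np.where(d < hbond_threshold, 2, 1)
    return SwitchEnergetics(np.array(elec), np.array(vdw), np.array(tot),
                            switch=switch, state_labels=labels)


# ---------------------------------------------------------------------------
# fluctuation / deviation profiles

def rmsf_profile(ensemble: EnsembleRecord, topology: Topology,
                 fit_selection: Optional[np.ndarray] = None,
                 measure_selection: Optional[np.ndarray] = None,
                 max_rounds: int = 10, tol: float = 1e-6) -> np.ndarray:
    """Per-bead RMSF (Å) about the iteratively superposed ensemble mean.

    Every conformation is superposed onto the running mean structure
    using ``fit_selection`` (default: catalytic-domain beads); the mean
    is recomputed until it shifts by less than ``tol`` Å or
    ``max_rounds`` is reached.
    """
    coords = ensemble.coordinates
    if coords.shape[0] < 2:
        raise ValueError("RMSF needs at least 2 conformations")
    if fit_selection is None:
        fit = np.nonzero(topology.domain_mask)[0]
    else:
        sel = np.asarray(fit_selection)
        fit = np.nonzero(sel)[0] if sel.dtype == bool else sel.astype(int)
    mean = coords[0].astype(float).copy()
    fitted = coords.astype(float).copy()
    for _ in range(max_rounds):
        ref = Conformation(mean)
        for k in range(coords.shape[0]):
            tr, _ = superpose_rmsd(Conformation(coords[k]), ref, fit)
            fitted[k] = tr.apply(coords[k])
        new_mean = fitted.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    rmsf = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    if measure_selection is not None:
        sel = np.asarray(measure_selection)
        idx = np.nonzero(sel)[0] if sel.dtype == bool else sel.astype(int)
        return rmsf[idx]
    return rmsf


def dihedral_angles(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion (degrees, (-180, 180]) for stacked point arrays."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1n)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    # IUPAC sign convention (matches the standard structural codes)
    ang = -np.degrees(np.arctan2(y, x))
    # collinear triples give a zero normal: undefined torsion
    degenerate = (np.linalg.norm(n1, axis=-1) < 1e-10) \
        | (np.linalg.norm(n2, axis=-1) < 1e-10)
    ang = np.where(degenerate, np.nan, ang)
    return np.where(ang <= -180.0, ang + 360.0, ang)


def hvr_pseudo_dihedrals(ensemble: EnsembleRecord, topology: Topology
                         ) -> pd.DataFrame:
    """Torsions of consecutive Cα quadruplets within the HVR.

    Returns a long-format frame (conformation, start_residue, angle_deg);
    undefined (collinear) torsions are NaN with a logged warning.
    """
    hvr_idx = np.nonzero(topology.hvr_mask)[0]
    if hvr_idx.size < 4:
        raise ValueError("HVR must contain at least 4 beads")
    res = topology.residue_index[hvr_idx]
    rows = []
    for k, coords in enumerate(ensemble.coordinates):
        p = coords[hvr_idx]
        ang = dihedral_angles(p[:-3], p[1:-2], p[2:-1], p[3:])
        for pos, a in zip(res[:-3], ang):
            rows.append((k, int(pos), float(a)))
    frame = pd.DataFrame(rows, columns=["conformation", "start_residue",
                                        "angle_deg"])
    n_bad = int(frame["angle_deg"].isna().sum())
    if n_bad:
        logger.warning("%d collinear quadruplet(s): torsion undefined", n_bad)
    return frame


def rmsd_statistics(ensemble: EnsembleRecord, reference: Conformation,
                    topology: Topology, selection: str = "catalytic_domain"
                    ) -> Tuple[float, float, np.ndarray]:
    """Mean ± sd of per-conformation RMSD to the starting structure.

    ``selection`` is 'catalytic_domain' (residues 1-166, HVR excluded)
    or 'full_length' (all protein beads); the fit uses the same
    selection as the measurement.
    """
    if ensemble.n_conformations == 0:
        raise ValueError("empty ensemble")
    if selection == "catalytic_domain":
        sel = np.nonzero(topology.domain_mask)[0]
    elif selection == "full_length":
        sel = np.nonzero(topology.protein_mask)[0]
    else:
        raise ValueError("selection must be 'catalytic_domain' or 'full_length'")
    vals = np.array([
        superpose_rmsd(Conformation(c), reference, sel)[1]
        for c in ensemble.coordinates])
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, vals


def classification_counts(ensemble: EnsembleRecord, topology: Topology,
                          cutoff: float = 8.0) -> Dict[str, int]:
    labels = [classify_hvr_binding(Conformation(c), topology, cutoff)
              for c in ensemble.coordinates]
    return {g: int(sum(1 for l in labels if l == g))
            for g in ("detached", "effector", "allosteric")}
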