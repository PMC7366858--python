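"""Synthetic coarse-grained model of full-length K-Ras4B.

One bead per residue at the Cα position.  The 166-residue catalytic
domain (effector lobe 1-86 with Switch I 30-38 and Switch II 59-76,
allosteric lobe 87-166) is generated by a seeded collapse of a
self-avoiding chain and stabilised by a harmonic native-contact
network.  The lysine-rich hypervariable region (HVR, residues 167-185)
is built extended, pointing away from the domain, and terminates in a
single hydrophobic farnesyl-mimic bead.  A nucleotide mimic
(base+ribose bead, α- and β-phosphate beads, plus a γ-phosphate bead
in the GTP state) and a Mg²⁺ bead sit in a surface pocket adjacent to
the switch regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

logger = logging.getLogger(__name__)

#: K-Ras4B residues 1-185 (mature protein before CAAX processing ends at
#: Cys185; the AAX tripeptide is removed post-translationally).
KRAS4B_SEQUENCE = (
    "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPTIEDSYRKQVVIDGET"
    "CLLDILDTAGQEEYSAMRDQYMRTGEGFLCVFAINNTKSFEDIHHYREQI"
    "KRVKDSEDVPMVLVGNKCDLPSRTVDTKQAQDLARSYGIPFIETSAKTRQ"
    "GVDDAFYTLVREIRKHKEKMSKDGKKKKKKSKTKC"
)

N_PROTEIN = 185
HVR_START = 167
DOMAIN_END = 166
EFFECTOR_LOBE = (1, 86)
ALLOSTERIC_LOBE = (87, 166)
SWITCH1 = (30, 38)
SWITCH2 = (59, 76)
GLY60 = 60

#: residue ids used for the hetero beads in PDB output / bookkeeping
RESID_NUCLEOTIDE = 201
RESID_MG = 202
RESID_FARNESYL = 203

REGION_NAMES = (
    "effector_lobe",
    "allosteric_lobe",
    "switch1",
    "switch2",
    "hvr",
    "nucleotide",
    "magnesium",
    "farnesyl",
)


@dataclass
class NonbondedSettings:
    """Global nonbonded parameters shared by all energy evaluations."""

    dielectric: float = 10.0
    #: Debye screening length mapping a 0.10 M monovalent salt background
    debye_length: float = 9.6
    cutoff: float = 12.0
    switch_on: float = 10.0
    hardcore: float = 0.7


@dataclass
class BuilderParams:
    """Settings for the synthetic system generator."""

    bond_length: float = 3.8
    bond_k: float = 100.0
    angle_k_domain: float = 10.0
    angle_k_hvr: float = 3.0
    native_contact_k: float = 1.0
    native_contact_cutoff: float = 9.0
    native_min_seq_sep: int = 3
    torsion_proxy_k: float = 0.3
    rg_target: float = 14.5
    bead_mass: float = 110.0
    lj_eps: float = 0.2
    lj_rmin_half: float = 2.5
    farnesyl_eps: float = 0.8
    farnesyl_rmin_half: float = 3.0
    farnesyl_mass: float = 205.0
    nucleotide_base_mass: float = 283.0
    phosphate_mass: float = 95.0
    mg_mass: float = 24.3
    phosphate_charge: float = -1.0
    gamma_charge: float = -1.0
    #: effective charge of the hydrated Mg²⁺ bead: the unresolved first
    #: coordination shell screens the bare +2 ion (a bare +2 point
    #: charge makes the acidic switch II loop collapse onto it, which
    #: inverts the nucleotide-state energetics)
    mg_charge: float = 1.0
    #: small positive partial charges on the beads lining the phosphate
    #: pocket, a proxy for the backbone amide donors (the Thr35 and
    #: Asp57-Gly60-loop amides) that coordinate the γ-phosphate; side
    #: chain charges are kept unchanged
    donor_charge: float = 0.6
    donor_residues: Tuple[int, ...] = (35, 59, 60, 61, 62, 63)
    #: leave the switch loops out of the native-contact network: their
    #: order is nucleotide-dependent in the emulated system (disordered
    #: without the γ anchor), not fold-enforced
    switch_loops_free: bool = True
    #: per-residue charge overrides, residue id -> charge
    charge_overrides: Dict[int, float] = field(default_factory=dict)
    #: cutoff used to assert that freshly built HVRs are detached
    detach_cutoff: float = 8.0
    contact_min_seq_sep: int = 4
    #: maximum number of distinct HVR orientation directions
    max_orientations: int = 6
    nonbonded: NonbondedSettings = field(default_factory=NonbondedSettings)


@dataclass
class Topology:
    """Static description of the bead system (masses, charges, bonded terms)."""

    n_beads: int
    masses: np.ndarray
    charges: np.ndarray
    residue_index: np.ndarray
    region: Dict[str, np.ndarray]
    bonds: np.ndarray          # (B, 2) int
    bond_k: np.ndarray
    bond_r0: np.ndarray
    angles: np.ndarray         # (A, 3) int
    angle_k: np.ndarray
    angle_t0: np.ndarray
    native_contacts: np.ndarray  # (C, 2) int
    contact_k: np.ndarray
    contact_r0: np.ndarray
    lj_eps: np.ndarray
    lj_rmin_half: np.ndarray
    state_tag: str
    sequence: str = KRAS4B_SEQUENCE
    nonbonded: NonbondedSettings = field(default_factory=NonbondedSettings)
    contact_min_seq_sep: int = 4

    def mask(self, *names: str) -> np.ndarray:
        """Union of the named region masks."""
        m = np.zeros(self.n_beads, dtype=bool)
        for name in names:
            m |= self.region[name]
        return m

    @property
    def protein_mask(self) -> np.ndarray:
        return self.mask("effector_lobe", "allosteric_lobe", "hvr")

    @property
    def domain_mask(self) -> np.ndarray:
        return self.mask("effector_lobe", "allosteric_lobe")

    @property
    def hvr_mask(self) -> np.ndarray:
        return self.region["hvr"]

    def labels_for(self, i: int) -> frozenset:
        return frozenset(n for n in REGION_NAMES if self.region[n][i])

    def bead_of_residue(self, resid: int) -> int:
        idx = np.nonzero(self.residue_index == resid)[0]
        if idx.size == 0:
            raise KeyError(f"no bead with residue id {resid}")
        return int(idx[0])


@dataclass
class Conformation:
    """Coordinates (Å) and optional velocities (Å/fs) for one structure."""

    coordinates: np.ndarray
    velocities: Optional[np.ndarray] = None
    provenance: str = ""
    residue_index: Optional[np.ndarray] = None

    def copy(self) -> "Conformation":
        return Conformation(
            coordinates=self.coordinates.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            provenance=self.provenance,
            residue_index=None if self.residue_index is None else self.residue_index.copy(),
        )


# ---------------------------------------------------------------------------
# charge assignment

_POSITIVE = set("KR")
_NEGATIVE = set("DE")


def residue_charges(sequence: str = KRAS4B_SEQUENCE,
                    donor_charge: float = 0.3,
                    donor_residues: Sequence[int] = (35, 59, 60, 61, 62, 63),
                    overrides: Optional[Dict[int, float]] = None) -> np.ndarray:
    """Per-residue charges: +1 Lys/Arg, -1 Asp/Glu, 0 otherwise.

    The beads lining the phosphate pocket additionally carry a small
    positive partial charge standing in for their backbone amide
    donors (Gly60 among them).
    """
    q = np.zeros(len(sequence))
    for i, aa in enumerate(sequence):
        if aa in _POSITIVE:
            q[i] = 1.0
        elif aa in _NEGATIVE:
            q[i] = -1.0
    for resid in donor_residues:
        q[resid - 1] += donor_charge
    if overrides:
        for resid, val in overrides.items():
            q[resid - 1] = val
    return q


# ---------------------------------------------------------------------------
# geometry helpers

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b (Rodrigues)."""
    a = _unit(a)
    b = _unit(b)
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any perpendicular axis for a half-turn
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis = _unit(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _self_avoiding_walk(n: int, bond: float, min_sep: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Seeded self-avoiding random walk with fixed bond length."""
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(500):
            step = rng.normal(size=3)
            step = bond * step / np.linalg.norm(step)
            trial = coords[i - 1] + step
            if i < 2 or np.min(np.linalg.norm(coords[: i - 1] - trial, axis=1)) > min_sep:
                coords[i] = trial
                break
        else:  # pragma: no cover - essentially unreachable with 500 tries
            raise RuntimeError("self-avoiding walk failed to extend")
    return coords


def _collapse(coords: np.ndarray, params: BuilderParams,
              sw1_idx: np.ndarray, sw2_idx: np.ndarray) -> np.ndarray:
    """Compact the chain to the target radius of gyration.

    Minimizes bonds + soft-sphere repulsion + an Rg restraint +
    a weak outward radial bias on the switch beads (surface loops),
    with the centroid pinned at the origin.
    """
    n = coords.shape[0]
    b = params.bond_length
    sigma = 4.0
    iu, ju = np.triu_indices(n, k=2)
    r_surf = params.rg_target * 1.18
    bias_idx = np.concatenate([sw1_idx, sw2_idx])

    def objective(x: np.ndarray):
        xyz = x.reshape(n, 3)
        g = np.zeros_like(xyz)
        # bonds
        dv = xyz[1:] - xyz[:-1]
        d = np.linalg.norm(dv, axis=1)
        e = 0.5 * params.bond_k * np.sum((d - b) ** 2)
        fb = (params.bond_k * (d - b) / d)[:, None] * dv
        g[1:] += fb
        g[:-1] -= fb
        # soft-sphere repulsion
        dvp = xyz[iu] - xyz[ju]
        dp = np.linalg.norm(dvp, axis=1)
        ov = dp < sigma
        if np.any(ov):
            delta = sigma - dp[ov]
            e += 10.0 * np.sum(delta ** 2)
            fp = (-20.0 * delta / dp[ov])[:, None] * dvp[ov]
            np.add.at(g, iu[ov], fp)
            np.add.at(g, ju[ov], -fp)
        # Rg restraint about the origin (d rg / d xyz_i = xyz_i / (n rg))
        r2 = np.sum(xyz ** 2, axis=1)
        rg = math.sqrt(np.mean(r2))
        e += 5.0 * n * (rg - params.rg_target) ** 2
        g += (10.0 * (rg - params.rg_target) / rg) * xyz
        # centroid pin
        c = xyz.mean(axis=0)
        e += 50.0 * float(np.dot(c, c))
        g += 100.0 * c / n
        # outward bias for switch beads (surface loops)
        if bias_idx.size:
            rb = np.linalg.norm(xyz[bias_idx], axis=1)
            low = rb < r_surf
            if np.any(low):
                delta = r_surf - rb[low]
                e += 0.5 * np.sum(delta ** 2)
                g[bias_idx[low]] += (-1.0 * delta / rb[low])[:, None] * xyz[bias_idx[low]]
        # the two switch loops line the same (nucleotide) site: pull
        # their centroids together
        if sw1_idx.size and sw2_idx.size:
            c1 = xyz[sw1_idx].mean(axis=0)
            c2 = xyz[sw2_idx].mean(axis=0)
            dv12 = c1 - c2
            d12 = float(np.linalg.norm(dv12))
            e += 8.0 * (d12 - 9.0) ** 2
            gc = 16.0 * (d12 - 9.0) * dv12 / d12
            g[sw1_idx] += gc / sw1_idx.size
            g[sw2_idx] -= gc / sw2_idx.size
        return e, g.ravel()

    res = _scipy_minimize(objective, coords.ravel(), jac=True, method="L-BFGS-B",
                          options={"maxiter": 4000, "ftol": 1e-12, "gtol": 1e-6})
    out = res.x.reshape(n, 3)
    return out - out.mean(axis=0)


def _zigzag_extend(start: np.ndarray, direction: np.ndarray, perp: np.ndarray,
                   n: int, bond: float, tilt_deg: float = 14.0,
                   twist_deg: float = 100.0) -> np.ndarray:
    """Extend n beads from `start` along `direction` as a gentle helix.

    Each step tilts off the axis by ``tilt_deg`` at an azimuth advancing
    by ``twist_deg``; the non-planar geometry gives every pseudo-torsion
    a well-defined restoring coupling.
    """
    beads = np.empty((n, 3))
    a = math.radians(tilt_deg)
    perp2 = np.cross(direction, perp)
    pos = start.copy()
    for i in range(n):
        az = math.radians(twist_deg) * i
        step = (math.cos(a) * direction
                + math.sin(a) * (math.cos(az) * perp + math.sin(az) * perp2))
        pos = pos + bond * step
        beads[i] = pos
    return beads


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    d = a[:, None, :] - b[None, :, :]
    return float(np.sqrt(np.min(np.sum(d * d, axis=-1))))


# ---------------------------------------------------------------------------
# main builder

def build_system(state: str, params: Optional[BuilderParams] = None,
                 seed: int = 0) -> Tuple[Topology, Conformation]:
    """Build the synthetic GDP- or GTP-state system.

    Pure function of (state, params, seed): the GTP topology differs
    from the GDP one built with the same seed by exactly one extra
    bead (the γ-phosphate mimic); the protein geometry is identical.
    """
    if state not in ("GDP", "GTP"):
        raise ValueError(f"invalid state tag {state!r}; expected 'GDP' or 'GTP'")
    params = params or BuilderParams()
    if params.rg_target <= 0:
        raise ValueError("domain compactness target (rg_target) must be positive")
    rng = np.random.default_rng(seed)

    blob_n = 162  # residues 1-162 collapse; 163-166 form the surface stalk
    saw = _self_avoiding_walk(blob_n, params.bond_length, 3.4, rng)
    sw1_idx = np.arange(SWITCH1[0] - 1, SWITCH1[1])
    sw2_idx = np.arange(SWITCH2[0] - 1, SWITCH2[1])
    blob = _collapse(saw, params, sw1_idx, sw2_idx)

    # --- stalk (163-166) + HVR (167-185): choose the clearest outward direction
    anchor = blob[blob_n - 1]
    base_dir = _unit(anchor - blob.mean(axis=0))
    candidates = _fibonacci_directions(64)
    candidates = candidates[candidates @ base_dir > 0.3]
    if candidates.shape[0] == 0:  # pragma: no cover
        candidates = base_dir[None, :]
    best, best_score = None, -np.inf
    for d in candidates:
        probes = anchor + np.outer(np.arange(1, 24) * params.bond_length, d)
        score = _min_dist(probes, blob[:-1])
        if score > best_score:
            best, best_score = d, score
    direction = _unit(best)
    ref = np.array([0.0, 0.0, 1.0]) if abs(direction[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    perp = _unit(np.cross(direction, ref))
    tail = _zigzag_extend(anchor, direction, perp, 23, params.bond_length)
    protein = np.vstack([blob, tail])  # (185, 3)

    # --- nucleotide pocket between the co-localised switch loops, the
    # γ site closest to Gly60 (its H-bond partner proxy)
    g60 = protein[GLY60 - 1]
    s1c = protein[sw1_idx].mean(axis=0)
    anchor_pt = 0.55 * g60 + 0.45 * s1c
    out_n = _unit(anchor_pt - blob.mean(axis=0))
    pocket_dir = _unit(s1c - g60)
    gamma_pos = g60 + 4.2 * _unit(2.0 * out_n + 0.8 * pocket_dir)
    beta_pos = gamma_pos + 3.1 * _unit(1.2 * out_n + 1.0 * pocket_dir)
    alpha_pos = beta_pos + 3.1 * _unit(1.0 * out_n + 1.2 * pocket_dir)
    base_pos = alpha_pos + 3.4 * _unit(1.2 * out_n + 0.6 * pocket_dir)
    if state == "GTP":
        mg_pos = 0.5 * (beta_pos + gamma_pos) + 2.6 * out_n
    else:
        mg_pos = beta_pos + 2.6 * out_n
    # clash resolution: lift any placed bead clear of the protein surface
    placed = [gamma_pos, beta_pos, alpha_pos, base_pos, mg_pos]
    for k, pos in enumerate(placed):
        for _ in range(20):
            if np.min(np.linalg.norm(protein - pos, axis=1)) >= 3.4:
                break
            pos = pos + 0.5 * out_n
        placed[k] = pos
    gamma_pos, beta_pos, alpha_pos, base_pos, mg_pos = placed

    farnesyl_pos = tail[-1] + params.bond_length * _unit(tail[-1] - tail[-2])

    # --- assemble bead arrays (protein, base, aP, bP, [gP], Mg, farnesyl)
    het: List[Tuple[np.ndarray, float, float, float, float, int, str]] = []
    # (pos, mass, charge, eps, rmin_half, resid, label)
    het.append((base_pos, params.nucleotide_base_mass, 0.0, params.lj_eps, 2.4,
                RESID_NUCLEOTIDE, "nucleotide"))
    het.append((alpha_pos, params.phosphate_mass, params.phosphate_charge,
                params.lj_eps, 1.8, RESID_NUCLEOTIDE, "nucleotide"))
    het.append((beta_pos, params.phosphate_mass, params.phosphate_charge,
                params.lj_eps, 1.8, RESID_NUCLEOTIDE, "nucleotide"))
    if state == "GTP":
        het.append((gamma_pos, params.phosphate_mass, params.gamma_charge,
                    params.lj_eps, 1.8, RESID_NUCLEOTIDE, "nucleotide"))
    het.append((mg_pos, params.mg_mass, params.mg_charge, 0.1, 2.0,
                RESID_MG, "magnesium"))
    het.append((farnesyl_pos, params.farnesyl_mass, 0.0, params.farnesyl_eps,
                params.farnesyl_rmin_half, RESID_FARNESYL, "farnesyl"))

    n_beads = N_PROTEIN + len(het)
    coords = np.vstack([protein] + [h[0] for h in het])
    masses = np.full(n_beads, params.bead_mass)
    charges = np.zeros(n_beads)
    charges[:N_PROTEIN] = residue_charges(KRAS4B_SEQUENCE, params.donor_charge,
                                          params.donor_residues,
                                          params.charge_overrides)
    lj_eps = np.full(n_beads, params.lj_eps)
    lj_rmin = np.full(n_beads, params.lj_rmin_half)
    residx = np.empty(n_beads, dtype=int)
    residx[:N_PROTEIN] = np.arange(1, N_PROTEIN + 1)
    region = {name: np.zeros(n_beads, dtype=bool) for name in REGION_NAMES}
    res = np.arange(1, N_PROTEIN + 1)
    region["effector_lobe"][:N_PROTEIN] = (res >= EFFECTOR_LOBE[0]) & (res <= EFFECTOR_LOBE[1])
    region["allosteric_lobe"][:N_PROTEIN] = (res >= ALLOSTERIC_LOBE[0]) & (res <= ALLOSTERIC_LOBE[1])
    region["switch1"][:N_PROTEIN] = (res >= SWITCH1[0]) & (res <= SWITCH1[1])
    region["switch2"][:N_PROTEIN] = (res >= SWITCH2[0]) & (res <= SWITCH2[1])
    region["hvr"][:N_PROTEIN] = res >= HVR_START
    for k, (_, m, q, eps, rh, rid, label) in enumerate(het):
        i = N_PROTEIN + k
        masses[i] = m
        charges[i] = q
        lj_eps[i] = eps
        lj_rmin[i] = rh
        residx[i] = rid
        region[label][i] = True

    # --- bonded terms
    bonds: List[Tuple[int, int, float]] = []
    for i in range(N_PROTEIN - 1):
        bonds.append((i, i + 1, params.bond_k))
    # weak 1-4 wells: a torsion proxy that removes the free internal
    # rotations of a bond+angle chain (the chain has no dihedral term);
    # ~0.2 kcal/mol per full rotation, so the tail stays thermally free
    for i in range(N_PROTEIN - 3):
        bonds.append((i, i + 3, params.torsion_proxy_k))
    i_base = N_PROTEIN
    i_alpha, i_beta = N_PROTEIN + 1, N_PROTEIN + 2
    i_gamma = N_PROTEIN + 3 if state == "GTP" else -1
    i_mg = n_beads - 2
    i_far = n_beads - 1
    bonds.append((i_base, i_alpha, 50.0))
    bonds.append((i_alpha, i_beta, 50.0))
    if state == "GTP":
        bonds.append((i_beta, i_gamma, 50.0))
        bonds.append((i_mg, i_gamma, 20.0))
    bonds.append((i_mg, i_beta, 20.0))
    # extra coordination anchors so Mg is not a free rotor about one bond
    bonds.append((i_mg, i_alpha, 5.0))
    bonds.append((i_mg, i_base, 5.0))
    bonds.append((N_PROTEIN - 1, i_far, 50.0))  # Cys185 - farnesyl
    # pyramid anchors pin the farnesyl cap's rotor degrees of freedom
    bonds.append((N_PROTEIN - 2, i_far, 5.0))
    bonds.append((N_PROTEIN - 3, i_far, 5.0))

    bond_idx = np.array([(i, j) for i, j, _ in bonds], dtype=int)
    bond_k = np.array([k for _, _, k in bonds])
    bond_r0 = np.linalg.norm(coords[bond_idx[:, 0]] - coords[bond_idx[:, 1]], axis=1)

    angles: List[Tuple[int, int, int, float]] = []
    for i in range(N_PROTEIN - 2):
        k_ang = params.angle_k_hvr if (i + 3) >= HVR_START else params.angle_k_domain
        angles.append((i, i + 1, i + 2, k_ang))
    ang_idx = np.array([(a, b, c) for a, b, c, _ in angles], dtype=int)
    ang_k = np.array([k for _, _, _, k in angles])
    u = coords[ang_idx[:, 0]] - coords[ang_idx[:, 1]]
    v = coords[ang_idx[:, 2]] - coords[ang_idx[:, 1]]
    cosang = np.sum(u * v, axis=1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    ang_t0 = np.arccos(np.clip(cosang, -1.0, 1.0))

    # --- native contacts: domain pairs within cutoff of the built structure
    dom = np.arange(blob_n + 4)  # residues 1-166 (blob + stalk)
    dd = coords[dom][:, None, :] - coords[dom][None, :, :]
    dist = np.sqrt(np.sum(dd * dd, axis=-1))
    switch_bead = region["switch1"] | region["switch2"]
    contacts: List[Tuple[int, int, float, float]] = []
    for a in range(len(dom)):
        for b in range(a + params.native_min_seq_sep, len(dom)):
            if params.switch_loops_free and (switch_bead[a] or switch_bead[b]):
                continue
            if dist[a, b] < params.native_contact_cutoff:
                contacts.append((a, b, params.native_contact_k, dist[a, b]))
    # nucleotide docking tethers: base, α- and β-phosphate each to their
    # three nearest non-switch domain beads (a P-loop stand-in; the
    # nucleotide is nanomolar-affinity bound and must not migrate).
    # The γ bead and Mg²⁺ stay untethered: their coupling to the switch
    # loops is the signal of interest.
    nonswitch = ~(region["switch1"] | region["switch2"])
    dom_ns = np.array([i for i in dom if nonswitch[i]], dtype=int)
    for bead in (i_base, i_alpha, i_beta):
        d = np.linalg.norm(coords[dom_ns] - coords[bead], axis=1)
        for j in np.argsort(d)[:5]:
            contacts.append((int(dom_ns[j]), bead, 10.0, float(d[j])))
    # Mg coordination by the domain (a Ser17/Asp57-like hold) keeps the
    # ion in the pocket instead of following the mobile switch loops
    d = np.linalg.norm(coords[dom_ns] - coords[i_mg], axis=1)
    for j in np.argsort(d)[:3]:
        contacts.append((int(dom_ns[j]), i_mg, 10.0, float(d[j])))
    con_idx = np.array([(a, b) for a, b, _, _ in contacts], dtype=int)
    con_k = np.array([k for _, _, k, _ in contacts])
    con_r0 = np.array([r for _, _, _, r in contacts])

    topo = Topology(
        n_beads=n_beads, masses=masses, charges=charges, residue_index=residx,
        region=region, bonds=bond_idx, bond_k=bond_k, bond_r0=bond_r0,
        angles=ang_idx, angle_k=ang_k, angle_t0=ang_t0,
        native_contacts=con_idx, contact_k=con_k, contact_r0=con_r0,
        lj_eps=lj_eps, lj_rmin_half=lj_rmin, state_tag=state,
        nonbonded=params.nonbonded, contact_min_seq_sep=params.contact_min_seq_sep,
    )
    conf = Conformation(coordinates=coords, provenance=f"built {state} seed={seed}",
                        residue_index=residx.copy())

    _assert_detached(topo, conf, params.detach_cutoff, params.contact_min_seq_sep)
    return topo, conf


def _assert_detached(topo: Topology, conf: Conformation, cutoff: float,
                     min_seq_sep: int) -> None:
    """Verify the built HVR has no domain contacts at the analysis cutoff."""
    x = conf.coordinates
    hvr = np.nonzero(topo.hvr_mask)[0]
    dom = np.nonzero(topo.domain_mask)[0]
    d = np.linalg.norm(x[dom][:, None, :] - x[hvr][None, :, :], axis=-1)
    sep = np.abs(topo.residue_index[dom][:, None] - topo.residue_index[hvr][None, :])
    counted = sep >= min_seq_sep
    if np.any(d[counted] < cutoff):
        raise RuntimeError(
            "built HVR is not detached from the domain at the analysis cutoff; "
            "increase the stalk length or reduce the cutoff")


def hvr_orientation_variants(topology: Topology, base: Conformation,
                             n_variants: int = 3, seed: int = 0) -> List[Conformation]:
    """Rigidly re-orient the extended HVR along distinct outward directions.

    The tail (residues 167-185 plus the farnesyl bead) is rotated about
    the Cα of residue 166; the catalytic domain is untouched.  Variant 0
    keeps the built orientation; further variants tilt the tail by 50°
    at azimuths spread around the stalk axis (seeded azimuthal offset).
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    params_max = 6
    if n_variants > params_max:
        raise ValueError(f"n_variants exceeds the configured maximum of {params_max}")
    x = base.coordinates
    pivot_idx = topology.bead_of_residue(DOMAIN_END)
    pivot = x[pivot_idx]
    tail_mask = topology.hvr_mask | topology.region["farnesyl"]
    axis = _unit(x[topology.bead_of_residue(HVR_START)] - pivot)

    rng = np.random.default_rng(seed)
    az0 = rng.uniform(0.0, 2.0 * math.pi)
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(axis, ref))
    e2 = np.cross(axis, e1)
    tilt = math.radians(50.0)

    directions = [axis]
    for tl in (tilt, 0.6 * tilt):
        for k in range(2 * params_max):
            az = az0 + math.pi * k / params_max
            d = math.cos(tl) * axis \
                + math.sin(tl) * (math.cos(az) * e1 + math.sin(az) * e2)
            directions.append(_unit(d))

    variants: List[Conformation] = []
    for d in directions:
        R = _rotation_between(axis, d)
        new = x.copy()
        new[tail_mask] = (R @ (x[tail_mask] - pivot).T).T + pivot
        conf = Conformation(coordinates=new,
                            provenance=f"{base.provenance} | "
                                       f"hvr-orientation {len(variants)}",
                            residue_index=None if base.residue_index is None
                            else base.residue_index.copy())
        try:
            _assert_detached(topology, conf, 8.0, topology.contact_min_seq_sep)
        except RuntimeError:
            continue  # this orientation clashes with the domain surface
        variants.append(conf)
        if len(variants) == n_variants:
            return variants
    raise RuntimeError(
        f"only {len(variants)} detached HVR orientations available "
        f"({n_variants} requested)")


# ---------------------------------------------------------------------------
# optional Cα-only PDB loading

def load_ca_structure(path, chain: str = "A") -> Conformation:
    """Load one bead per residue at the Cα position from a PDB file.

    Residues lacking a Cα atom are skipped with a logged warning; atoms
    are kept in file order (insertion codes preserved by order).
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1)
    chain_atoms = atoms[atoms.chain_id == chain]
    if chain_atoms.array_length() == 0:
        raise ValueError(f"chain {chain!r} not present or empty in {path}")
    ca = chain_atoms[chain_atoms.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError(f"no Cα atoms found in chain {chain!r} of {path}")
    n_res = len(struc.get_residues(chain_atoms)[0])
    n_missing = n_res - ca.array_length()
    if n_missing > 0:
        logger.warning("%d residue(s) in chain %s lack a Cα atom and were skipped",
                       n_missing, chain)
    return Conformation(coordinates=np.asarray(ca.coord, dtype=float),
                        provenance=f"ca from {path} chain {chain}",
                        residue_index=np.asarray(ca.res_id, dtype=int))
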