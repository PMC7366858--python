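"""Small hand-built systems used as oracles across the test suite."""

import numpy as np

from mdenm.model import (Conformation, NonbondedSettings, REGION_NAMES,
                         Topology)


def toy_topology(coords, bonds=(), angles=(), contacts=(), charges=None,
                 masses=None, eps=None, rmin_half=None, nonbonded=None,
                 state="GDP", residue_index=None, regions=None,
                 contact_min_seq_sep=4):
    """Build an arbitrary small Topology + Conformation.

    ``bonds``/``contacts`` are (i, j, k) or (i, j, k, r0) tuples (r0
    defaults to the built distance); ``angles`` are (i, j, k, k_force)
    or (i, j, k, k_force, theta0).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)

    def _dist(i, j):
        return float(np.linalg.norm(coords[i] - coords[j]))

    def _angle(i, j, k):
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.arccos(np.clip(c, -1, 1)))

    b_idx, b_k, b_r0 = [], [], []
    for b in bonds:
        i, j, kf = b[0], b[1], b[2]
        b_idx.append((i, j))
        b_k.append(kf)
        b_r0.append(b[3] if len(b) > 3 else _dist(i, j))
    a_idx, a_k, a_t0 = [], [], []
    for a in angles:
        i, j, k, kf = a[0], a[1], a[2], a[3]
        a_idx.append((i, j, k))
        a_k.append(kf)
        a_t0.append(a[4] if len(a) > 4 else _angle(i, j, k))
    c_idx, c_k, c_r0 = [], [], []
    for c in contacts:
        i, j, kf = c[0], c[1], c[2]
        c_idx.append((i, j))
        c_k.append(kf)
        c_r0.append(c[3] if len(c) > 3 else _dist(i, j))

    region = {name: np.zeros(n, dtype=bool) for name in REGION_NAMES}
    if regions:
        for name, mask in regions.items():
            region[name] = np.asarray(mask, dtype=bool)

    topo = Topology(
        n_beads=n,
        masses=np.full(n, 110.0) if masses is None else np.asarray(masses, float),
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        residue_index=(np.arange(1, n + 1) if residue_index is None
                       else np.asarray(residue_index, int)),
        region=region,
        bonds=np.array(b_idx, int).reshape(-1, 2),
        bond_k=np.array(b_k, float),
        bond_r0=np.array(b_r0, float),
        angles=np.array(a_idx, int).reshape(-1, 3),
        angle_k=np.array(a_k, float),
        angle_t0=np.array(a_t0, float),
        native_contacts=np.array(c_idx, int).reshape(-1, 2),
        contact_k=np.array(c_k, float),
        contact_r0=np.array(c_r0, float),
        lj_eps=np.zeros(n) if eps is None else np.asarray(eps, float),
        lj_rmin_half=np.full(n, 2.5) if rmin_half is None
        else np.asarray(rmin_half, float),
        state_tag=state,
        nonbonded=nonbonded or NonbondedSettings(),
        contact_min_seq_sep=contact_min_seq_sep,
    )
    return topo, Conformation(coords.copy())


def dimer(k=100.0, r0=3.8, mass=110.0, sep=None, charges=(0.0, 0.0), eps=0.0):
    """Two beads joined by one harmonic bond."""
    sep = r0 if sep is None else sep
    coords = [[0.0, 0.0, 0.0], [sep, 0.0, 0.0]]
    return toy_topology(coords, bonds=[(0, 1, k, r0)],
                        charges=charges, masses=[mass, mass],
                        eps=[eps, eps])


def elastic_network(n=8, seed=0, k=5.0, cutoff=8.0):
    """Pure harmonic network at its own minimum (no LJ, no charges)."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 6.0, size=(n, 3))
    # spread beads a little so the network is nonlinear and connected
    coords[:, 0] += np.arange(n) * 1.5
    contacts = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                contacts.append((i, j, k))
    return toy_topology(coords, contacts=contacts)


def random_cluster(n=5, seed=0, charges=True, spread=6.0):
    """Random beads with charges and LJ for brute-force pair-sum oracles."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, spread, size=(n, 3))
    # keep beads apart so LJ stays tame
    for _ in range(200):
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, 9e9)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] > 3.5:
            break
        coords[i] += rng.normal(scale=1.0, size=3)
    q = rng.choice([-1.0, 0.0, 1.0], size=n) if charges else np.zeros(n)
    return toy_topology(coords, charges=q, eps=np.full(n, 0.2))


def brute_pair_energy(topo, coords, idx_a, idx_b):
    """Independent pair-by-pair sum of the switched LJ + screened Coulomb."""
    nb = topo.nonbonded
    elec = vdw = 0.0
    excl = set()
    for i, j in topo.bonds:
        excl.add((min(i, j), max(i, j)))
    for i, _, k in topo.angles:
        excl.add((min(i, k), max(i, k)))
    for i, j in topo.native_contacts:
        excl.add((min(i, j), max(i, j)))
    for i in idx_a:
        for j in idx_b:
            if (min(i, j), max(i, j)) in excl or i == j:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r >= nb.cutoff:
                continue
            if r > nb.switch_on:
                rc2, ron2, r2 = nb.cutoff ** 2, nb.switch_on ** 2, r * r
                s = (rc2 - r2) ** 2 * (rc2 + 2 * r2 - 3 * ron2) / (rc2 - ron2) ** 3
            else:
                s = 1.0
            rm = topo.lj_rmin_half[i] + topo.lj_rmin_half[j]
            e_ij = np.sqrt(topo.lj_eps[i] * topo.lj_eps[j])
            vdw += s * e_ij * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
            elec += s * 332.0637 * topo.charges[i] * topo.charges[j] \
                * np.exp(-r / nb.debye_length) / (nb.dielectric * r)
    return elec, vdw, elec + vdw
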