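"""Ensemble analyses against brute-force / closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from helpers import toy_topology
from mdenm.analysis import (classify_hvr_binding,
                            contact_map, dihedral_angles,
                            hvr_interaction_energies, hvr_pseudo_dihedrals,
                            nucleotide_switch_energies, rmsd_statistics,
                            rmsf_profile, superpose_rmsd)
from mdenm.engine import EnsembleRecord
from mdenm.model import Conformation


def record_of(coords_list):
    return EnsembleRecord(np.asarray(coords_list, dtype=float),
                          pd.DataFrame(), pd.DataFrame())


def mini_protein(domain_pos, hvr_pos, domain_res=None, hvr_res=None,
                 effector_count=None, **kw):
    """Tiny labelled topology: some domain beads + some HVR beads."""
    nd, nh = len(domain_pos), len(hvr_pos)
    coords = np.vstack([domain_pos, hvr_pos])
    if domain_res is None:
        domain_res = list(range(1, nd + 1))
    if hvr_res is None:
        hvr_res = list(range(167, 167 + nh))
    n_eff = nd if effector_count is None else effector_count
    regions = {
        "effector_lobe": [True] * n_eff + [False] * (nd - n_eff) + [False] * nh,
        "allosteric_lobe": [False] * n_eff + [True] * (nd - n_eff) + [False] * nh,
        "hvr": [False] * nd + [True] * nh,
    }
    return toy_topology(coords, residue_index=list(domain_res) + list(hvr_res),
                        regions=regions, **kw)


# ---------------------------------------------------------------------------
# superposition

def test_superpose_recovers_rigid_transform(gdp_build):
    topo, conf = gdp_build
    R = Rotation.from_euler("xyz", [30, -45, 80], degrees=True).as_matrix()
    moved = conf.coordinates @ R.T + np.array([5.0, -3.0, 12.0])
    _, rmsd = superpose_rmsd(Conformation(moved), conf)
    assert rmsd < 1e-9


def test_superpose_invariant_under_rigid_transform_of_mobile(gdp_build):
    topo, conf = gdp_build
    rng = np.random.default_rng(0)
    mobile = Conformation(conf.coordinates + rng.normal(scale=0.5,
                          size=conf.coordinates.shape))
    _, rmsd0 = superpose_rmsd(mobile, conf)
    R = Rotation.from_euler("zyx", [12, 150, -70], degrees=True).as_matrix()
    moved = Conformation(mobile.coordinates @ R.T + 100.0)
    _, rmsd1 = superpose_rmsd(moved, conf)
    assert abs(rmsd0 - rmsd1) < 1e-9


def test_superpose_matches_rotation_grid_oracle():
    """4-point fixture: Kabsch RMSD matches exhaustive grid minimization."""
    ref = np.array([[0.0, 0, 0], [3, 0, 0], [3, 4, 0], [0, 4, 2.0]])
    mob = np.array([[0.2, 0.1, -0.3], [3.1, -0.2, 0.4],
                    [2.7, 4.2, 0.1], [-0.3, 3.8, 2.2]])
    _, rmsd = superpose_rmsd(Conformation(mob), Conformation(ref))
    refc = ref - ref.mean(0)
    mobc = mob - mob.mean(0)

    def rot_rmsd(angles):
        R = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
        return np.sqrt(np.mean(np.sum((mobc @ R.T - refc) ** 2, axis=1)))

    best, best_ang = np.inf, None
    grid = np.linspace(-180, 180, 37)
    for a in grid:
        for b in np.linspace(-90, 90, 19):
            for c in grid:
                r = rot_rmsd([a, b, c])
                if r < best:
                    best, best_ang = r, [a, b, c]
    # simplex refinement of the best grid cell (still Kabsch-free)
    from scipy.optimize import minimize as scipy_min
    res = scipy_min(rot_rmsd, best_ang, method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-12})
    assert rmsd == pytest.approx(min(best, res.fun), abs=1e-3)


def test_superpose_degenerate_selection_falls_back(caplog):
    ref = Conformation(np.array([[0.0, 0, 0], [1, 0, 0]]))
    mob = Conformation(np.array([[5.0, 5, 5], [6, 5, 5]]))
    tr, rmsd = superpose_rmsd(mob, ref)
    np.testing.assert_allclose(tr.rotation, np.eye(3))
    assert rmsd == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# contacts

def test_contact_map_strict_cutoff():
    """One HVR bead at 5.4 Å: counted below a 5.5 Å cutoff, not at 5.6 Å."""
    topo, conf = mini_protein([[0, 0, 0], [20, 0, 0]], [[5.4, 0, 0], [40, 0, 0]])
    rec = record_of([conf.coordinates])
    cm = contact_map(rec, topo, cutoff=5.5)
    assert cm.counts.sum() == 1 and cm.counts[0, 0] == 1
    cm2 = contact_map(rec, topo, cutoff=5.39)
    assert cm2.counts.sum() == 0


def test_contact_map_counts_capped_by_ensemble_size():
    topo, conf = mini_protein([[0, 0, 0]], [[5.0, 0, 0]])
    rec = record_of([conf.coordinates] * 7)
    cm = contact_map(rec, topo, cutoff=8.0)
    assert cm.n_conformations == 7
    assert cm.counts.max() == 7


@given(st.integers(min_value=0, max_value=10 ** 6))
@settings(max_examples=15, deadline=None)
def test_contact_map_matches_brute_force(seed):
    """Population counts equal an exhaustive all-pairs re-count."""
    rng = np.random.default_rng(seed)
    nd, nh, nc = 6, 4, 10
    topo, _ = mini_protein(np.zeros((nd, 3)), np.zeros((nh, 3)))
    ensemble = rng.uniform(0, 15, size=(nc, nd + nh, 3))
    cm = contact_map(record_of(ensemble), topo, cutoff=6.0)
    dom_res = np.arange(1, nd + 1)
    hvr_res = np.arange(167, 167 + nh)
    expected = np.zeros((nd, nh), dtype=int)
    for c in ensemble:
        for i in range(nd):
            for j in range(nh):
                if abs(dom_res[i] - hvr_res[j]) < topo.contact_min_seq_sep:
                    continue
                if np.linalg.norm(c[i] - c[nd + j]) < 6.0:
                    expected[i, j] += 1
    np.testing.assert_array_equal(cm.counts, expected)


def test_classify_majority_and_tiebreak():
    # 3 effector contacts vs 1 allosteric -> effector
    dom = [[0, 0, 0], [5, 0, 0], [10, 0, 0], [100, 0, 0]]
    hvr = [[2.5, 3, 0], [7.5, 3, 0], [5.0, -3, 0], [103, 0, 0]]
    topo, conf = mini_protein(dom, hvr, effector_count=3)
    assert classify_hvr_binding(conf, topo, cutoff=8.0) == "effector"
    # equal counts, allosteric side closer -> allosteric
    dom = [[0.0, 0, 0], [30.0, 0, 0]]
    hvr = [[7.0, 0, 0], [24.5, 0, 0]]
    topo, conf = mini_protein(dom, hvr, effector_count=1)
    assert classify_hvr_binding(conf, topo, cutoff=8.0) == "allosteric"
    # far tail -> detached
    topo, conf = mini_protein([[0, 0, 0]], [[50.0, 0, 0]])
    assert classify_hvr_binding(conf, topo, cutoff=8.0) == "detached"


def test_classification_partition(campaign_results):
    """detached + effector + allosteric counts sum to the ensemble size."""
    for (seed, state), res in campaign_results.items():
        counts = res["classification"]
        assert sum(counts.values()) == res["mdenm"].n_conformations


# ---------------------------------------------------------------------------
# interaction-energy statistic

def _charged_fixture():
    dom = [[0.0, 0, 0], [6.0, 0, 0], [60, 0, 0]]
    hvr = [[3.0, 4, 0], [9.0, 4, 0]]
    return mini_protein(dom, hvr, effector_count=2,
                        charges=[-1, 1, 0, 1, 1],
                        eps=np.full(5, 0.2))


def test_delta_e_centering_and_point_mass():
    topo, conf = _charged_fixture()
    base = conf.coordinates
    detached = base.copy()
    detached[3:] += np.array([0, 200.0, 0])  # move tail far away
    ens = record_of([base, base, detached, detached, detached])
    dists = hvr_interaction_energies(ens, topo, cutoff=8.0, min_reference=1)
    assert dists["detached"].values.mean() == pytest.approx(0.0, abs=1e-12)
    # identical bound conformations -> point-mass distribution
    assert dists["effector"].n == 2
    assert np.ptp(dists["effector"].values) == 0.0


def test_delta_e_matches_hand_computed_pair_sums():
    """5-conformation toy: ΔE equals brute pair sums minus reference mean."""
    from helpers import brute_pair_energy

    topo, conf = _charged_fixture()
    rng = np.random.default_rng(5)
    confs = []
    for k in range(5):
        c = conf.coordinates.copy()
        if k >= 3:
            c[3:] += np.array([0, 300.0 + 10 * k, 0])  # detached reference
        else:
            c[3:] += rng.normal(scale=0.3, size=(2, 3))
        confs.append(c)
    ens = record_of(confs)
    dists = hvr_interaction_energies(ens, topo, cutoff=8.0, min_reference=1)
    tail_idx = [3, 4]
    env_idx = [0, 1, 2]
    expected_bound = [brute_pair_energy(topo, c, tail_idx, env_idx)[2]
                      for c in confs]
    ref_mean = np.mean(expected_bound[3:])
    got = np.sort(dists["effector"].values)
    want = np.sort(np.array(expected_bound[:3]) - ref_mean)
    np.testing.assert_allclose(got, want, atol=1e-10)
    assert dists["effector"].reference_n == 2


def test_empty_detached_reference_aborts():
    topo, conf = _charged_fixture()
    ens = record_of([conf.coordinates] * 3)
    with pytest.raises(ValueError, match="detached"):
        hvr_interaction_energies(ens, topo, cutoff=8.0)


# ---------------------------------------------------------------------------
# nucleotide-switch energetics

def test_nucleotide_switch_energy_matches_pair_sum(gtp_build):
    from helpers import brute_pair_energy

    topo, conf = gtp_build
    ens = record_of([conf.coordinates])
    out = nucleotide_switch_energies(ens, topo, "II")
    nuc = np.nonzero(topo.mask("nucleotide", "magnesium"))[0]
    sw = np.nonzero(topo.region["switch2"])[0]
    e, v, t = brute_pair_energy(topo, conf.coordinates, nuc, sw)
    assert out.total[0] == pytest.approx(t, abs=1e-9)


def test_gdp_lacks_gamma_terms(gdp_build, gtp_build):
    """The γ-dependent contribution exists only in the GTP topology."""
    gdp, _ = gdp_build
    gtp, _ = gtp_build
    assert int(gdp.region["nucleotide"].sum()) == 3
    assert int(gtp.region["nucleotide"].sum()) == 4
    ens = record_of([_.coordinates for _ in ()] or
                    [gdp_build[1].coordinates])
    out = nucleotide_switch_energies(ens, gdp, "II")
    assert out.state_labels is None
    with pytest.raises(ValueError):
        nucleotide_switch_energies(ens, gdp, "II", label_states=True)


def test_state1_state2_proxy_labels(gtp_build):
    topo, conf = gtp_build
    gamma = int(np.nonzero(topo.region["nucleotide"])[0][-1])
    g60 = topo.bead_of_residue(60)
    direction = conf.coordinates[gamma] - conf.coordinates[g60]
    direction /= np.linalg.norm(direction)
    near = conf.coordinates.copy()
    near[gamma] = near[g60] + 4.0 * direction
    far = conf.coordinates.copy()
    far[gamma] = far[g60] + 9.0 * direction
    ens = record_of([near, far])
    out = nucleotide_switch_energies(ens, topo, "II", hbond_threshold=4.6)
    assert list(out.state_labels) == [2, 1]


# ---------------------------------------------------------------------------
# RMSF / dihedrals / RMSD

def test_rmsf_zero_for_identical_structures(gdp_build):
    topo, conf = gdp_build
    ens = record_of([conf.coordinates] * 4)
    rmsf = rmsf_profile(ens, topo)
    assert np.abs(rmsf).max() < 1e-9


def test_rmsf_two_conformation_oracle(gdp_build):
    """±d displacement of one bead (after fitting) gives RMSF d."""
    topo, conf = gdp_build
    bead = int(np.nonzero(topo.hvr_mask)[0][-1])  # far from the fit region
    d = 1.7
    a = conf.coordinates.copy()
    b = conf.coordinates.copy()
    a[bead, 2] += d
    b[bead, 2] -= d
    rmsf = rmsf_profile(ens := record_of([a, b]), topo)
    assert rmsf[bead] == pytest.approx(d, abs=1e-6)
    others = np.ones(topo.n_beads, dtype=bool)
    others[bead] = False
    assert rmsf[others].max() < 1e-6


def test_dihedral_planar_fixtures():
    trans = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0.0]])
    assert dihedral_angles(*trans) == pytest.approx(180.0)
    cis = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0.0]])
    assert dihedral_angles(*cis) == pytest.approx(0.0)


@given(st.integers(min_value=0, max_value=10 ** 6))
@settings(max_examples=30, deadline=None)
def test_dihedral_matches_independent_formula(seed):
    """Random quadruplets agree with MDAnalysis' dihedral routine."""
    from MDAnalysis.lib.distances import calc_dihedrals

    rng = np.random.default_rng(seed)
    p = rng.uniform(-5, 5, size=(4, 3))
    got = dihedral_angles(p[0], p[1], p[2], p[3])
    if np.isnan(got):
        return
    # independent float64 construction: signed angle between the two
    # bond-plane normals about the central bond
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    ref = np.degrees(np.arctan2(
        np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)), np.dot(n1, n2)))
    diff = (got - ref + 180.0) % 360.0 - 180.0
    assert abs(diff) < 1e-9
    # cross-check against MDAnalysis (float32 internals)
    mda = np.degrees(calc_dihedrals(p[0][None], p[1][None],
                                    p[2][None], p[3][None]))[0]
    diff = (got - mda + 180.0) % 360.0 - 180.0
    assert abs(diff) < 1e-3


def test_hvr_pseudo_dihedral_table(gdp_build):
    topo, conf = gdp_build
    ens = record_of([conf.coordinates] * 2)
    frame = hvr_pseudo_dihedrals(ens, topo)
    n_hvr = int(topo.hvr_mask.sum())
    assert len(frame) == 2 * (n_hvr - 3)
    assert frame["start_residue"].min() == 167
    assert frame["start_residue"].max() == 185 - 3
    ok = frame["angle_deg"].dropna()
    assert ((ok > -180.0) & (ok <= 180.0)).all()


def test_rmsd_statistics_oracles(gdp_build):
    topo, conf = gdp_build
    mean, sd, vals = rmsd_statistics(record_of([conf.coordinates]), conf,
                                     topo, "catalytic_domain")
    assert mean == pytest.approx(0.0, abs=1e-9) and sd == 0.0
    # 3-conformation toy: mean/sd match a hand computation
    rng = np.random.default_rng(8)
    confs = [conf.coordinates + rng.normal(scale=s,
             size=conf.coordinates.shape) for s in (0.1, 0.4, 0.8)]
    mean, sd, vals = rmsd_statistics(record_of(confs), conf, topo,
                                     "full_length")
    sel = np.nonzero(topo.protein_mask)[0]
    hand = [superpose_rmsd(Conformation(c), conf, sel)[1] for c in confs]
    assert mean == pytest.approx(np.mean(hand))
    assert sd == pytest.approx(np.std(hand, ddof=1))


def test_domain_selection_excludes_hvr(gdp_build):
    """Catalytic-domain RMSD ignores tail motion entirely."""
    topo, conf = gdp_build
    moved = conf.coordinates.copy()
    moved[topo.hvr_mask] += 25.0
    mean, sd, _ = rmsd_statistics(record_of([moved]), conf, topo,
                                  "catalytic_domain")
    assert mean == pytest.approx(0.0, abs=1e-9)
    mean_full, _, _ = rmsd_statistics(record_of([moved]), conf, topo,
                                      "full_length")
    assert mean_full > 1.0
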