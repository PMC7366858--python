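"""Campaign orchestration: configuration schema, planning, execution,
manifest writing.

A campaign runs, per nucleotide state: build → minimize → normal modes
→ excitation-direction generation (diversity filtered) → equilibration
→ MDeNM replicas (round-robin over the HVR orientation variants) →
plain-MD controls → all ensemble analyses → CSV/JSON reports, with a
manifest holding the configuration snapshot, derived seeds, output
checksums and warnings.  Identical configuration + seed reproduces
identical outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import yaml

from . import analysis as ana
from .energy import MinimizeSettings, minimize
from .engine import (CampaignConfig, EnsembleRecord, generate_directions,
                     IntegratorSettings, integrate_segment,
                     maxwell_boltzmann_velocities, run_mdenm_replica,
                     run_plain_md)
from .io import export_reports, write_structure
from .model import BuilderParams, NonbondedSettings, Topology, build_system, \
    hvr_orientation_variants
from .modes import compute_hessian, compute_modes

logger = logging.getLogger(__name__)

#: paper-style staged positional restraints for structure preparation
STAGED_MINIMIZE = MinimizeSettings(restraint_schedule=(10.0, 1.0, 0.1))


class ConfigError(ValueError):
    """A named configuration field failed validation."""


@dataclass
class AnalysisSettings:
    contact_cutoff: float = 8.0
    hbond_state_threshold: float = 4.5
    min_reference: int = 100


@dataclass
class CampaignSpec:
    """Validated campaign configuration."""

    seed: int = 0
    states: List[str] = field(default_factory=lambda: ["GDP", "GTP"])
    n_orientations: int = 3
    equilibration_steps: int = 25000
    n_modes: int = 10
    zero_tolerance: float = 1e-6
    builder: BuilderParams = field(default_factory=BuilderParams)
    mdenm: CampaignConfig = field(default_factory=CampaignConfig)
    md_control_runs: int = 1
    md_control_steps: Optional[int] = None
    md_control_stride: Optional[int] = None
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    write_pdb: bool = True
    write_dcd: bool = False

    def validate(self) -> None:
        for s in self.states:
            if s not in ("GDP", "GTP"):
                raise ConfigError(f"states: invalid state tag {s!r}")
        if self.n_orientations < 1:
            raise ConfigError("n_orientations: must be >= 1")
        if self.equilibration_steps < 0:
            raise ConfigError("equilibration_steps: must be >= 0")
        if self.n_modes < 1:
            raise ConfigError("n_modes: must be >= 1")
        if self.builder.rg_target <= 0:
            raise ConfigError("builder.rg_target: must be positive")


_NESTED = {
    "builder": BuilderParams,
    "mdenm": CampaignConfig,
    "analysis": AnalysisSettings,
}


def _build_dataclass(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    bad = set(data) - names
    if bad:
        raise ConfigError(f"{where}: unknown field(s) {sorted(bad)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def load_config(path: Union[str, Path]) -> CampaignSpec:
    """Parse and validate a YAML campaign configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> CampaignSpec:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    data = dict(raw)
    kwargs = {}
    for key, cls in _NESTED.items():
        if key in data:
            sub = data.pop(key)
            if key == "builder" and "nonbonded" in sub:
                sub = dict(sub)
                sub["nonbonded"] = _build_dataclass(
                    NonbondedSettings, sub["nonbonded"], "builder.nonbonded")
            kwargs[key] = _build_dataclass(cls, sub, key)
    spec = _build_dataclass(CampaignSpec, {**data, **kwargs}, "config")
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# planning (manifest arithmetic, no trajectories required)

@dataclass
class CampaignPlan:
    n_states: int
    n_orientations: int
    n_replicas: int
    excitations_per_replica: int

    @property
    def replicas_per_state(self) -> int:
        return self.n_replicas

    @property
    def conformations_per_state(self) -> int:
        return self.n_replicas * self.excitations_per_replica

    @property
    def total_replica_trajectories(self) -> int:
        return self.n_states * self.n_replicas

    @property
    def total_conformations(self) -> int:
        return self.n_states * self.conformations_per_state

    def to_dict(self) -> Dict[str, int]:
        return {
            "n_states": self.n_states,
            "n_orientations": self.n_orientations,
            "replicas_per_state": self.replicas_per_state,
            "excitations_per_replica": self.excitations_per_replica,
            "conformations_per_state": self.conformations_per_state,
            "total_replica_trajectories": self.total_replica_trajectories,
            "total_conformations": self.total_conformations,
        }


def plan_campaign(spec: CampaignSpec) -> CampaignPlan:
    """Declared campaign bookkeeping derived from the configuration alone."""
    return CampaignPlan(
        n_states=len(spec.states),
        n_orientations=spec.n_orientations,
        n_replicas=spec.mdenm.n_replicas,
        excitations_per_replica=spec.mdenm.excitations_per_replica,
    )


# ---------------------------------------------------------------------------
# execution

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _seed_for(master: int, *stream: int) -> int:
    return int(np.random.SeedSequence([master, *stream]).generate_state(1)[0]
               % (2 ** 31))


def run_state(spec: CampaignSpec, state: str, out_dir: Optional[Path] = None
              ) -> Dict[str, object]:
    """Run one nucleotide state of the campaign; return in-memory results."""
    cfg = spec.mdenm
    builder_seed = _seed_for(spec.seed, 0)
    topo, built = build_system(state, spec.builder, seed=builder_seed)
    # orientation variants come from the built structure (guaranteed
    # detached); each variant is then minimized on its own
    variants = hvr_orientation_variants(topo, built, spec.n_orientations,
                                        seed=_seed_for(spec.seed, 1))
    # modes per orientation variant (the excitation fields live on the
    # variant's own reference geometry)
    modesets = []
    for v in variants:
        vmin = minimize(topo, v, STAGED_MINIMIZE)
        H = compute_hessian(topo, vmin)
        modesets.append(compute_modes(H, topo, spec.n_modes,
                                      spec.zero_tolerance, reference=vmin))
    minimized = modesets[0].reference
    settings = IntegratorSettings(thermostat=True, temperature=cfg.temperature,
                                  friction_ps=cfg.friction_ps,
                                  timestep_fs=cfg.timestep_fs)
    starts = []
    for m, ms in enumerate(modesets):
        start = ms.reference.copy()
        rng = np.random.default_rng(_seed_for(spec.seed, 5, m))
        start.velocities = maxwell_boltzmann_velocities(
            topo, cfg.temperature, rng)
        if spec.equilibration_steps:
            start, _ = integrate_segment(topo, start, spec.equilibration_steps,
                                         settings,
                                         seed=_seed_for(spec.seed, 6, m))
        starts.append(start)
    # directions per variant, round-robin replica assignment
    per_variant = [cfg.n_replicas // spec.n_orientations
                   + (1 if r < cfg.n_replicas % spec.n_orientations else 0)
                   for r in range(spec.n_orientations)]
    records = []
    replica_id = 0
    state_code = 0 if state == "GDP" else 1
    for m, (ms, n_dir) in enumerate(zip(modesets, per_variant)):
        if n_dir == 0:
            continue
        directions = generate_directions(
            ms, n_dir, cfg, seed=_seed_for(spec.seed, 2, state_code, m))
        for d in directions:
            rec = run_mdenm_replica(
                topo, starts[m], ms, d, cfg,
                seed=_seed_for(spec.seed, 3, state_code, replica_id),
                state=state, model=m, replica=replica_id)
            records.append(rec)
            replica_id += 1
    mdenm_ens = EnsembleRecord.merge(records)
    md_records = []
    for r in range(spec.md_control_runs):
        md_records.append(run_plain_md(
            topo, starts[r % spec.n_orientations], cfg,
            seed=_seed_for(spec.seed, 4, state_code, r),
            n_steps=spec.md_control_steps, stride=spec.md_control_stride,
            state=state, model=r % spec.n_orientations, replica=r))
    md_ens = EnsembleRecord.merge(md_records)
    results = analyse_state(spec, state, topo, minimized, mdenm_ens, md_ens)
    results.update({"topology": topo, "minimized": minimized,
                    "mdenm": mdenm_ens, "md": md_ens})
    return results


def analyse_state(spec: CampaignSpec, state: str, topo: Topology, minimized,
                  mdenm_ens: EnsembleRecord, md_ens: EnsembleRecord
                  ) -> Dict[str, object]:
    cutoff = spec.analysis.contact_cutoff
    cmap = ana.contact_map(mdenm_ens, topo, cutoff)
    cmap_md = ana.contact_map(md_ens, topo, cutoff)
    counts = ana.classification_counts(mdenm_ens, topo, cutoff)
    try:
        hvr_e = ana.hvr_interaction_energies(mdenm_ens, topo, cutoff,
                                             spec.analysis.min_reference)
    except ValueError:
        logger.warning("%s: empty detached reference group; "
                       "HVR energy distributions skipped", state)
        hvr_e = None
    sw = {}
    for which in ("I", "II"):
        sw[which] = ana.nucleotide_switch_energies(
            mdenm_ens, topo, which, spec.analysis.hbond_state_threshold)
    rmsf_mdenm = ana.rmsf_profile(mdenm_ens, topo)
    rmsf_md = ana.rmsf_profile(md_ens, topo)
    rmsd_dom = ana.rmsd_statistics(mdenm_ens, minimized, topo,
                                   "catalytic_domain")
    rmsd_full = ana.rmsd_statistics(mdenm_ens, minimized, topo, "full_length")
    dihedrals = ana.hvr_pseudo_dihedrals(mdenm_ens, topo)
    return {
        "contact_map": cmap, "contact_map_md": cmap_md,
        "classification": counts, "hvr_energies": hvr_e,
        "switch_energies": sw, "rmsf_mdenm": rmsf_mdenm, "rmsf_md": rmsf_md,
        "rmsd_domain": rmsd_dom, "rmsd_full": rmsd_full,
        "dihedrals": dihedrals,
    }


def run_campaign(config: Union[str, Path, CampaignSpec],
                 out_dir: Union[str, Path] = "campaign_out"
                 ) -> Dict[str, object]:
    """Execute the full campaign and write reports + manifest.

    Returns the manifest dictionary (also written to manifest.json).
    """
    spec = config if isinstance(config, CampaignSpec) else load_config(config)
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    plan = plan_campaign(spec)
    files: Dict[str, str] = {}
    summary: Dict[str, object] = {"plan": plan.to_dict()}
    import pandas as pd

    for state in spec.states:
        res = run_state(spec, state)
        topo = res["topology"]
        tag = state.lower()
        tables = {
            f"{tag}_contact_map_mdenm": res["contact_map"].to_frame(),
            f"{tag}_contact_map_md": res["contact_map_md"].to_frame(),
            f"{tag}_rmsf": _rmsf_frame(topo, res["rmsf_mdenm"], res["rmsf_md"]),
            f"{tag}_dihedrals": res["dihedrals"],
            f"{tag}_diagnostics": res["mdenm"].diagnostics,
            f"{tag}_rmsd": _rmsd_frame(res),
        }
        if res["hvr_energies"] is not None:
            tables[f"{tag}_hvr_energies"] = _energy_frame(res["hvr_energies"])
        written = export_reports(tables, out)
        if spec.write_pdb:
            p = out / f"{tag}_mdenm_ensemble.pdb"
            write_structure(topo, res["mdenm"], p)
            written[f"{tag}_ensemble_pdb"] = p
        if spec.write_dcd:
            p = out / f"{tag}_mdenm_ensemble.dcd"
            write_structure(topo, res["mdenm"], p, fmt="dcd")
            written[f"{tag}_ensemble_dcd"] = p
        for name, p in written.items():
            files[name] = str(p)
        summary[state] = _state_summary(res)
    summary_path = out / "campaign_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    files["campaign_summary"] = str(summary_path)
    manifest = {
        "config": _spec_to_dict(spec),
        "plan": plan.to_dict(),
        "seeds": {"master": spec.seed,
                  "builder": _seed_for(spec.seed, 0),
                  "orientations": _seed_for(spec.seed, 1)},
        "files": {name: {"path": p, "sha256": _sha256(Path(p))}
                  for name, p in files.items()},
        "elapsed_s": round(time.time() - t0, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest


def _rmsf_frame(topo: Topology, rmsf_mdenm, rmsf_md):
    import pandas as pd

    prot = np.nonzero(topo.protein_mask)[0]
    return pd.DataFrame({
        "residue": topo.residue_index[prot],
        "rmsf_mdenm": rmsf_mdenm[prot],
        "rmsf_md": rmsf_md[prot],
    })


def _rmsd_frame(res):
    import pandas as pd

    return pd.DataFrame({
        "selection": ["catalytic_domain", "full_length"],
        "mean": [res["rmsd_domain"][0], res["rmsd_full"][0]],
        "sd": [res["rmsd_domain"][1], res["rmsd_full"][1]],
    })


def _energy_frame(dists):
    import pandas as pd

    rows = []
    for group, dist in dists.items():
        for v, e in zip(dist.values, dist.bound_energies):
            rows.append((group, v, e))
    return pd.DataFrame(rows, columns=["group", "delta_e", "e_bound"])


def _state_summary(res) -> Dict[str, object]:
    counts = res["classification"]
    total = max(1, sum(counts.values()))
    out = {
        "classification": counts,
        "group_fractions": {k: v / total for k, v in counts.items()},
        "rmsd_domain_mean": res["rmsd_domain"][0],
        "rmsd_domain_sd": res["rmsd_domain"][1],
        "rmsd_full_mean": res["rmsd_full"][0],
        "rmsd_full_sd": res["rmsd_full"][1],
        "switch_energies": {k: v.summary()
                            for k, v in res["switch_energies"].items()},
        "dissipation_flags": int(res["mdenm"].diagnostics
                                 ["dissipation_flag"].sum()),
    }
    if res["hvr_energies"] is not None:
        out["hvr_energies"] = {k: v.summary()
                               for k, v in res["hvr_energies"].items()}
    return out


def _spec_to_dict(spec: CampaignSpec) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(spec),
                                 default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
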