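"""MDeNM engine: excitation directions, diversity filtering, velocity
kicks, Langevin/NVE propagation, replicas and plain-MD controls.

An excitation direction is a randomized linear combination of the
selected low-frequency modes.  Each mode's Cartesian field is
pre-normalised to a 1 Å-RMSD displacement; the combination drawn with
coefficients uniform on [-1, 1]^m therefore carries an intrinsic
amplitude (typically ~1.8 Å RMSD at unit displacement).  The diversity
filter compares structures displaced along candidate and accepted
combinations and keeps a candidate only when every pairwise RMSD
exceeds the threshold (1.65 Å at a 1 Å displacement by default).

Each excitation kicks the velocities along the direction by exactly
the amount that raises the kinetic energy by (3/2) N kB ΔT (ΔT = 10 K
by default, cross-term included), followed by a thermostatted
relaxation segment (2,500 steps × 2 fs = 5 ps by default); the
projected kinetic energy along the direction is recorded so that
non-dissipated excitation energy can be flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .constants import KB, KE_CONV
from .energy import packed
from .model import Conformation, Topology
from .modes import ModeSet

logger = logging.getLogger(__name__)


class IntegrationError(RuntimeError):
    pass


@dataclass
class ExcitationDirection:
    """A normalized mode combination with its intrinsic amplitude."""

    coefficients: np.ndarray    # unit Euclidean norm, one weight per mode
    amplitude: float            # Å: all-bead RMSD of the raw combination at s=1
    cartesian_unit: np.ndarray  # (N, 3); displacing by s gives RMSD exactly s
    accepted: bool = False
    seed: int = 0

    @property
    def displacement_field(self) -> np.ndarray:
        """Cartesian field of the raw combination (RMSD = amplitude at s=1)."""
        return self.amplitude * self.cartesian_unit


@dataclass
class CampaignConfig:
    n_replicas: int = 8
    excitations_per_replica: int = 32
    delta_T: float = 10.0           # K per kick
    relaxation_steps: int = 2500
    timestep_fs: float = 2.0
    temperature: float = 300.0
    friction_ps: float = 1.0
    diversity_displacement: float = 1.0   # Å
    diversity_threshold: float = 1.65     # Å
    max_direction_attempts: int = 5000
    master_seed: int = 0

    def __post_init__(self):
        for name in ("n_replicas", "excitations_per_replica", "relaxation_steps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.diversity_threshold <= 0:
            raise ValueError("diversity_threshold must be positive")

    @property
    def relaxation_time_ps(self) -> float:
        return self.relaxation_steps * self.timestep_fs / 1000.0

    @property
    def conformations_per_replica(self) -> int:
        return self.excitations_per_replica


@dataclass
class IntegratorSettings:
    thermostat: bool = True
    temperature: float = 300.0
    friction_ps: float = 1.0
    timestep_fs: float = 2.0


@dataclass
class SegmentDiagnostics:
    kinetic_energy_trace: np.ndarray          # kcal/mol per step
    projected_ke_trace: Optional[np.ndarray]  # kcal/mol per step, or None


@dataclass
class EnsembleRecord:
    """Conformations with provenance plus per-cycle diagnostics."""

    coordinates: np.ndarray           # (n_conf, N, 3)
    meta: pd.DataFrame                # state, model, replica, excitation
    diagnostics: pd.DataFrame

    @property
    def n_conformations(self) -> int:
        return self.coordinates.shape[0]

    @classmethod
    def merge(cls, records: Sequence["EnsembleRecord"]) -> "EnsembleRecord":
        return cls(
            coordinates=np.concatenate([r.coordinates for r in records]),
            meta=pd.concat([r.meta for r in records], ignore_index=True),
            diagnostics=pd.concat([r.diagnostics for r in records],
                                  ignore_index=True),
        )


# ---------------------------------------------------------------------------
# direction sampling and diversity filtering

def sample_direction(modes: ModeSet, seed: int) -> ExcitationDirection:
    """Draw a randomized mode combination (seeded, deterministic)."""
    rng = np.random.default_rng(seed)
    m = modes.n_modes
    n = modes.n_beads
    for _ in range(100):
        c = rng.uniform(-1.0, 1.0, size=m)
        norm = float(np.linalg.norm(c))
        if norm > 1e-3:
            break
        logger.info("degenerate mode combination resampled (|c| = %.2e)", norm)
    else:  # pragma: no cover
        raise RuntimeError("could not draw a non-degenerate combination")
    field_ = np.tensordot(c, modes.cartesian_shapes, axes=(0, 0))
    amplitude = float(np.sqrt(np.sum(field_ ** 2) / n))
    unit = field_ * (math.sqrt(n) / np.linalg.norm(field_))
    return ExcitationDirection(coefficients=c / norm, amplitude=amplitude,
                               cartesian_unit=unit, accepted=False, seed=seed)


def displaced_rmsd(a: ExcitationDirection, b: ExcitationDirection,
                   displacement: float = 1.0) -> float:
    """RMSD between structures displaced along two directions (no re-fit).

    Both displacements scale each direction's own combination field by
    ``displacement``; the shared reference cancels.
    """
    n = a.cartesian_unit.shape[0]
    diff = displacement * (a.displacement_field - b.displacement_field)
    return float(np.sqrt(np.sum(diff ** 2) / n))


def diversity_filter(candidate: ExcitationDirection,
                     accepted: Sequence[ExcitationDirection],
                     displacement: float = 1.0,
                     threshold: float = 1.65) -> bool:
    """Accept a candidate iff its displaced structure is more than
    ``threshold`` Å RMSD away from every accepted one (first always passes)."""
    if displacement <= 0:
        raise ValueError("displacement must be positive")
    ok = all(displaced_rmsd(candidate, a, displacement) > threshold
             for a in accepted)
    candidate.accepted = bool(ok)
    return candidate.accepted


def generate_directions(modes: ModeSet, n_directions: int,
                        config: Optional[CampaignConfig] = None,
                        seed: int = 0) -> List[ExcitationDirection]:
    """Sample directions through the diversity filter until n are accepted."""
    config = config or CampaignConfig()
    ss = np.random.SeedSequence([seed, 2])
    child_seeds = ss.generate_state(config.max_direction_attempts) % (2 ** 31)
    accepted: List[ExcitationDirection] = []
    for s in child_seeds:
        cand = sample_direction(modes, int(s))
        if diversity_filter(cand, accepted, config.diversity_displacement,
                            config.diversity_threshold):
            accepted.append(cand)
            if len(accepted) == n_directions:
                return accepted
    raise RuntimeError(
        f"only {len(accepted)}/{n_directions} directions accepted within "
        f"{config.max_direction_attempts} attempts")


# ---------------------------------------------------------------------------
# excitation and integration

def kinetic_energy(masses: np.ndarray, velocities: np.ndarray) -> float:
    """Kinetic energy in kcal/mol for velocities in Å/fs."""
    return float(0.5 * KE_CONV * np.sum(masses[:, None] * velocities ** 2))


def excitation_target(n_beads: int, delta_T: float) -> float:
    """Kinetic energy (kcal/mol) equivalent to a ΔT temperature increment."""
    return 1.5 * n_beads * KB * delta_T


def excite_velocities(topology: Topology, velocities: np.ndarray,
                      direction: ExcitationDirection, delta_T: float
                      ) -> np.ndarray:
    """Add λ·û to the velocities so the kinetic-energy jump equals
    (3/2) N kB ΔT exactly (cross-term included, positive root)."""
    if delta_T < 0:
        raise ValueError("delta_T must be non-negative")
    v = np.array(velocities, dtype=np.float64)
    if delta_T == 0:
        return v
    u = direction.cartesian_unit
    m = topology.masses
    a = KE_CONV * float(np.sum(m[:, None] * u * u))
    b = KE_CONV * float(np.sum(m[:, None] * v * u))
    target = excitation_target(topology.n_beads, delta_T)
    disc = b * b + 2.0 * a * target
    assert disc >= 0.0, "no positive root for the excitation amplitude"
    lam = (-b + math.sqrt(disc)) / a
    return v + lam * u


def maxwell_boltzmann_velocities(topology: Topology, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    sigma = np.sqrt(KB * temperature / (topology.masses * KE_CONV))
    return rng.normal(size=(topology.n_beads, 3)) * sigma[:, None]


def integrate_segment(topology: Topology, conf: Conformation, n_steps: int,
                      settings: Optional[IntegratorSettings] = None,
                      seed: int = 0,
                      project_direction: Optional[np.ndarray] = None
                      ) -> Tuple[Conformation, SegmentDiagnostics]:
    """Propagate for n_steps (BAOAB Langevin or velocity-Verlet NVE)."""
    settings = settings or IntegratorSettings()
    x = np.array(conf.coordinates, dtype=np.float64)
    v = (np.array(conf.velocities, dtype=np.float64)
         if conf.velocities is not None else np.zeros_like(x))
    if n_steps == 0:
        return (Conformation(x, v, conf.provenance, conf.residue_index),
                SegmentDiagnostics(np.empty(0), None))
    ff = packed(topology)
    record = project_direction is not None
    u = (np.ascontiguousarray(project_direction, dtype=np.float64)
         if record else np.zeros((1, 3)))
    trace = np.zeros(n_steps if record else 1)
    temp_trace = np.zeros(n_steps)
    bad = _kernels.run_segment(
        x, v, ff.masses, *ff.kernel_args(),
        n_steps, float(settings.timestep_fs),
        float(settings.friction_ps) * 1e-3,
        KB * float(settings.temperature),
        bool(settings.thermostat), int(seed) % (2 ** 31),
        u, record, trace, temp_trace)
    if bad >= 0:
        raise IntegrationError(f"numerical blow-up at step {bad}")
    return (Conformation(x, v, conf.provenance, conf.residue_index),
            SegmentDiagnostics(temp_trace, trace if record else None))


def kinetic_temperature(topology: Topology, ke: np.ndarray) -> np.ndarray:
    """Instantaneous kinetic temperature (K) from kinetic energy (kcal/mol)."""
    return ke / (1.5 * topology.n_beads * KB)


# ---------------------------------------------------------------------------
# replicas

def run_mdenm_replica(topology: Topology, start: Conformation, modes: ModeSet,
                      direction: ExcitationDirection, config: CampaignConfig,
                      seed: int, state: str = "", model: int = 0,
                      replica: int = 0) -> EnsembleRecord:
    """One MDeNM replica: repeated {kick along the direction, relax}.

    Records the conformation at the end of each relaxation segment and
    per-cycle diagnostics (injected kinetic energy, final projected
    kinetic energy, dissipation flag).
    """
    if not direction.accepted:
        raise ValueError("direction has not been accepted by the diversity filter")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    settings = IntegratorSettings(thermostat=True,
                                  temperature=config.temperature,
                                  friction_ps=config.friction_ps,
                                  timestep_fs=config.timestep_fs)
    conf = start.copy()
    if conf.velocities is None:
        conf.velocities = maxwell_boltzmann_velocities(
            topology, config.temperature, rng)
    baseline = 0.5 * KB * config.temperature  # one collective DOF
    coords, rows, diag = [], [], []
    for cycle in range(config.excitations_per_replica):
        ke_before = kinetic_energy(topology.masses, conf.velocities)
        conf.velocities = excite_velocities(topology, conf.velocities,
                                            direction, config.delta_T)
        injected = kinetic_energy(topology.masses, conf.velocities) - ke_before
        seg_seed = int(rng.integers(0, 2 ** 31))
        try:
            conf, seg = integrate_segment(
                topology, conf, config.relaxation_steps, settings,
                seed=seg_seed, project_direction=direction.cartesian_unit)
        except IntegrationError as exc:
            raise IntegrationError(
                f"replica {replica} cycle {cycle}: {exc}") from exc
        final_proj = float(seg.projected_ke_trace[-1])
        flagged = final_proj > 2.0 * baseline
        if flagged:
            logger.warning(
                "dissipation check: replica %d cycle %d retains %.3f kcal/mol "
                "along the excitation direction (baseline %.3f)",
                replica, cycle, final_proj, baseline)
        coords.append(conf.coordinates.copy())
        rows.append((state, model, replica, cycle))
        diag.append((replica, cycle, injected, final_proj, flagged))
    meta = pd.DataFrame(rows, columns=["state", "model", "replica", "excitation"])
    diagnostics = pd.DataFrame(
        diag, columns=["replica", "cycle", "injected_ke",
                       "final_projected_ke", "dissipation_flag"])
    return EnsembleRecord(np.array(coords), meta, diagnostics)


def run_plain_md(topology: Topology, start: Conformation,
                 config: CampaignConfig, seed: int,
                 n_steps: Optional[int] = None, stride: Optional[int] = None,
                 state: str = "", model: int = 0, replica: int = 0
                 ) -> EnsembleRecord:
    """Thermostatted control run; conformations saved every ``stride`` steps.

    Defaults match one MDeNM replica's total length and recording rate,
    giving the same number of recorded conformations.
    """
    if n_steps is None:
        n_steps = config.excitations_per_replica * config.relaxation_steps
    if stride is None:
        stride = config.relaxation_steps
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    settings = IntegratorSettings(thermostat=True,
                                  temperature=config.temperature,
                                  friction_ps=config.friction_ps,
                                  timestep_fs=config.timestep_fs)
    conf = start.copy()
    if conf.velocities is None:
        conf.velocities = maxwell_boltzmann_velocities(
            topology, config.temperature, rng)
    n_frames = n_steps // stride
    coords, rows, diag = [], [], []
    for frame in range(n_frames):
        seg_seed = int(rng.integers(0, 2 ** 31))
        conf, _ = integrate_segment(topology, conf, stride, settings,
                                    seed=seg_seed)
        coords.append(conf.coordinates.copy())
        rows.append((state, model, replica, frame))
    meta = pd.DataFrame(rows, columns=["state", "model", "replica", "excitation"])
    diagnostics = pd.DataFrame(
        columns=["replica", "cycle", "injected_ke", "final_projected_ke",
                 "dissipation_flag"])
    return EnsembleRecord(np.array(coords), meta, diagnostics)
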