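# Methods

`mdenm` implements Molecular Dynamics with excited Normal Modes (MDeNM)
— enhanced conformational sampling by periodic kinetic-energy kicks
along randomized combinations of low-frequency normal modes — together
with the ensemble analyses used to characterise nucleotide-dependent
autoinhibition of full-length K-Ras4B: catalytic-domain/HVR contact
population maps, HVR interaction-energy distributions against a
detached-tail reference, nucleotide–switch energetics with a
state-1/state-2 hydrogen-bond proxy, RMSF/RMSD statistics and Cα
pseudo-dihedral profiles.  The sampling protocol and analyses operate
on any `Topology`/`Conformation` pair; the package ships a synthetic
coarse-grained K-Ras4B mimic so the full pipeline runs and is tested
end to end on a desk-scale system.

## The coarse-grained K-Ras4B mimic

One bead per residue at the Cα position (uniform 110 amu), 185 protein
beads carrying the K-Ras4B sequence, plus a nucleotide mimic (merged
base+ribose bead, α-, β- and — in the GTP state — γ-phosphate beads),
a hydrated Mg²⁺ bead and a terminal farnesyl bead bonded to Cys185.
Region labels follow the standard Ras conventions: effector lobe
1–86 (Switch I 30–38, Switch II 59–76), allosteric lobe 87–166, HVR
167–185.  The GTP and GDP topologies built from the same seed differ
by exactly one bead (the γ-phosphate, charge −1).

**Geometry.**  Residues 1–162 are generated as a seeded self-avoiding
walk collapsed to a target radius of gyration (default 14.5 Å, the
scale of the real G-domain) by a penalised quasi-Newton minimisation.
Two biases shape the blob the way the real fold is shaped: the switch
loops are pushed to the surface (they are surface loops) and their
centroids are drawn together (they line a single nucleotide site).
Residues 163–166 form a short straight stalk off the surface — a
mimic of the protruding α5 C-terminus — and the HVR (167–185) extends
from it as a gentle helix pointing away from the domain, so every
freshly built conformation has zero domain–HVR contacts at the
analysis cutoff.  The nucleotide is placed in the groove between the
two switch loops with the γ bead 4.2 Å from the Gly60 bead, its
hydrogen-bond partner proxy.

**Interactions.**  Bonds, angles and Gō-style native-contact wells are
harmonic, `E = ½k(x−x₀)²`.  Native contacts are all residue-1–166
pairs within 9 Å of the built structure (|i−j| ≥ 3, k = 1 kcal/mol/Å²)
— an elastic network that keeps the domain near its fold while the
switch loops, deliberately contact-poor at the surface, stay mobile.
The chain additionally carries weak 1–4 distance wells
(k = 0.3 kcal/mol/Å², ≈2 kT per full rotation): a Cα chain with only
bonds and angles has free internal rotations, which are unphysical
zero-stiffness directions — they let a minimiser drift the detached
tail onto the domain and contaminate the zero-mode subspace.
Nonbonded pairs combine a 12-6 potential (per-bead ε and r_min/2,
Lorentz-style combination) with Debye-screened Coulomb
`332.0637·q₁q₂·exp(−r/λ)/(ε_r·r)`; λ = 9.6 Å maps the 0.10 M salt
background of the reference conditions, the dielectric defaults to 10
(an effective implicit-solvent value), and both terms are tapered to
zero with a CHARMM-style switching function between 10 and 12 Å.
Charges are sequence-derived (+1 Lys/Arg, −1 Asp/Glu): the HVR is net
+9, the lysine-rich tail of the real protein.

Five choices deserve explicit justification because simpler variants
fail in instructive ways:

- **Pocket donors.**  The beads lining the phosphate pocket (Thr35 and
  residues 59–63) carry +0.6 partial charges representing their
  backbone amide donors.  In the real protein the γ-phosphate is read
  out by backbone hydrogen bonds (Gly60 N–H among them), not by side
  chains; without the donor proxies a Cα monopole model sees only the
  acidic Switch II side chains and the γ channel cannot be expressed.
  The magnitude is calibrated so the γ–Gly60 proxy bond is a few
  kcal/mol — the strength of a real backbone hydrogen-bond network —
  which makes state 2 (bond formed) the majority state at 300 K, as
  it is in the system being emulated; at +0.3 the proxy bond holds
  less than 6% of the time and the model misrepresents the state-2
  dominance of the active form.
- **Phosphate bead size.**  Phosphate beads use r_min/2 = 1.8 Å: with
  the generic 2.2 Å the γ+Gly60 contact distance (4.7 Å) would exceed
  the 4.5 Å hydrogen-bond-proxy threshold, making state 2
  geometrically unreachable regardless of energetics.
- **Hydrated Mg²⁺.**  The Mg bead uses an effective charge of +1 with
  an enlarged radius and harmonic coordination to the phosphates and
  nearest non-switch domain beads (the Ser17/Asp57-like hold).  A
  bare +2 point charge is wrong at this resolution: the acidic Switch
  II loop collapses onto it, producing ≈−10 kcal/mol artifactual
  GDP–Switch II energies that invert the nucleotide dependence.
- **Rigid nucleotide docking.**  Base, α- and β-phosphate are each
  tethered to their five nearest non-switch domain beads (k = 10):
  the real nucleotide is buried and nanomolar-bound, and a loosely
  docked mimic swings several Å, carrying the γ anchor with it.  The
  γ bead and Mg are never tethered to switch beads — their coupling
  to the switches is the observable.
- **Free switch loops.**  The switch regions are excluded from the
  native-contact network: their order is nucleotide-dependent in the
  emulated system (Switch II is disordered in the GDP state), so it
  must come from the γ anchor, not be enforced by the fold.  With
  fold contacts on the loops the GDP/GTP flexibility difference
  cannot exist at this resolution.

**What the mimic does and does not emulate.**  It reproduces the
architecture that drives the paper-scale physics: a stable two-lobe
domain, mobile surface switch loops coupled to the nucleotide, a
positively charged disordered tail that can engage either lobe, and a
γ-phosphate that both stiffens Switch II (through the donor contacts)
and changes the system charge by −1.  It does not emulate side-chain
packing, hydrogen-bond directionality, explicit solvent, secondary
structure or the true fold, so passing tests demonstrate that the
protocol and analyses behave correctly and that the qualitative
nucleotide-state patterns emerge from the stated mechanism — not that
the real protein's maps or energies are reproduced quantitatively.

## Structure preparation

Preparation minimises under positional restraints that decrease in
stages (10, 1, 0.1 kcal/mol/Å², then unrestrained), the classic
preparation schedule, followed by steepest descent and L-BFGS until
every force component is below 1e-4 kcal/mol/Å.  The staging keeps the
soft detached tail inside its own basin; unrestrained minimisation
from scratch may let the tail associate with the domain for some
seeds, which mirrors what happens during the reference protocol's own
equilibration and is handled downstream by ensemble classification
rather than forbidden.

## Normal modes

The Hessian is assembled by central finite differences of the analytic
forces (h = 1e-4 Å; validated against the diatomic closed form 2k/m
and by translational invariance) and symmetrised.  The mass-weighted
matrix is diagonalised with `scipy.linalg.eigh`.  When a reference
structure is supplied, the rigid-body subspace (3 translations + the
independent rotations; rank 5 for linear molecules) is projected out
before diagonalisation — the floppy tail possesses genuine internal
modes softer than any practical eigenvalue threshold, so threshold
classification alone miscounts; without a reference the eigenvalue
threshold (default 1e-6) is used, which is exact for the toy systems.
The 10 lowest internal modes (configurable) are retained, each with a
Cartesian displacement field normalised so a 1 Å displacement gives an
all-bead RMSD of exactly 1 Å, plus per-bead amplitudes for ranking.

## Excitation directions and the diversity filter

A direction is a randomized linear combination of the selected modes
with coefficients drawn uniformly on [−1, 1]^m.  Because each mode's
field is 1 Å-RMSD-normalised, the combination carries an intrinsic
amplitude (typically ≈1.8 Å RMSD at unit displacement); the stored
`cartesian_unit` is re-normalised to RMSD 1 and the amplitude kept
alongside.  The diversity filter displaces the reference along the
candidate's and every accepted direction's *own* combination field
(scaled by the 1 Å displacement setting) and accepts the candidate
only when every pairwise RMSD — plain coordinate arithmetic, all
beads, no re-superposition — exceeds 1.65 Å.  The amplitude term is
essential: for amplitude-normalised fields the 1.65 Å criterion is
unsatisfiable beyond three directions (pairwise RMSD of unit fields is
√(2−2cosθ) ≤ 2, and a positive-semidefinite Gram argument caps any
set with pairwise cosθ < −0.36 at three members), whereas amplitude
variation makes 50+ accepted directions routine, with the filter
rejecting near-parallel or low-amplitude draws.

## The MDeNM engine

Dynamics uses velocity Verlet (NVE) or BAOAB-split Langevin dynamics
(300 K, friction 1 ps⁻¹, 2 fs steps by default) in compiled kernels.
Each excitation adds λ·û to the velocities with λ the positive root of
the quadratic that makes the kinetic-energy jump exactly
(3/2)·N·k_B·ΔT, cross-term included (ΔT = 10 K ⇒ 5.66 kcal/mol for
the 190-bead GDP system); N counts all mobile beads.  A replica
repeats {kick along its fixed direction, relax 2,500 steps = 5 ps}
32 times, recording the conformation after every relaxation and the
kinetic energy projected on the excitation direction; a cycle whose
final projected energy exceeds twice the single-degree-of-freedom
thermal baseline (½k_BT) is flagged as incompletely dissipated — a
logged warning, not an error.  Plain-MD controls use the identical
integrator with excitation disabled and matched recording stride, so
MDeNM and control ensembles have equal conformation counts.

Seeds: every stage derives its generator from
`SeedSequence([master, stage, …])`; identical configuration + master
seed reproduces a campaign bit for bit.

## Analyses

*Contacts.*  A domain residue and an HVR residue are in contact when
any inter-bead distance is strictly below the cutoff.  The all-atom
criterion of 5.5 Å between heavy atoms has no direct Cα equivalent;
the Cα default is 8 Å (configurable).  Pairs closer than 4 in sequence
are never counted: the covalent anchor around residue 166–167 is
otherwise always "in contact" and the detached class could not exist.
Classification per conformation: detached (no contacts), otherwise
the lobe with the majority of contacts, ties broken by the smaller
minimum distance.

*HVR energetics.*  ΔE_HVR = E_bound − ⟨E_non-bound⟩, where E is the
electrostatic + vdW interaction of the tail (HVR residues plus the
farnesyl bead) with everything else, and the reference mean is taken
over the campaign's detached conformations (a configurable minimum,
default 100, warns when the reference group is thin; with implicit
solvent the environment is protein + nucleotide + Mg only).

*Nucleotide–switch energetics.*  Electrostatic + vdW interaction of
{nucleotide beads + Mg} with each switch region per conformation.  For
GTP systems each conformation is labelled state 2 when the γ–Gly60
bead distance is below 4.5 Å (the CG proxy for the γ-phosphate–Gly60
backbone hydrogen bond; the all-atom donor–acceptor distance of
≈2.8 Å applies only to atomistic inputs), else state 1.

*RMSF.*  Conformations are superposed on the catalytic-domain beads
onto an iteratively refined mean structure (≤10 rounds, 1e-6 Å
convergence); RMSF is computed about the converged mean.  *RMSD*
statistics fit and measure on the same selection (catalytic domain =
residues 1–166, or full length) against the starting structure;
spread is the sample standard deviation.  *Pseudo-dihedrals* are the
signed torsions of sliding Cα quadruplets within the HVR, IUPAC sign
convention, in (−180°, 180°]; collinear quadruplets are recorded as
missing.  Superposition uses Kabsch via
`scipy.spatial.transform.Rotation.align_vectors`, with a
translation-only fallback (and warning) for degenerate selections.

## Campaign scale and runtime choices

The reference protocol's scale (264 replicas × 32 excitations =
8,448 conformations per system, three HVR orientations, microsecond
aggregate) is a configuration, verified as manifest arithmetic.  The
default test-scale campaign runs 8 replicas × 32 excitations per
state with one HVR orientation and a 50 ps equilibration; the
stochastic pattern tests aggregate three master seeds (11, 12, 13,
fixed a priori).  Statements the test suite makes at this scale are
qualitative and directional (MDeNM HVR RMSF > 1.5× control; GTP
Switch II energy below GDP; GTP Switch II RMSF below GDP); the
per-seed scatter at 256 conformations per state is substantial and is
averaged over seeds before comparison.

## Numerical notes and limitations

- Forces are the exact gradient (finite-difference validated at
  1e-4 kcal/mol/Å); the switching taper is C¹, adequate for dynamics,
  minimisation and finite-difference Hessians.
- NVE drift on the full system is <0.05% of the kinetic energy over
  10,000 × 2 fs steps; BAOAB reproduces the dimer bond-length
  Boltzmann distribution (KS < 0.05 at 10⁴ samples).
- Hard-core overlaps (<0.7 Å) abort energy evaluation with the
  offending pair; integration aborts on non-finite or >10⁶ Å
  coordinates with replica/cycle context.
- The detached class can be rare in sticky parameterisations (the
  tail binds strongly at ε_r = 10); the Eq.-1 reference then rests on
  few conformations and its warning fires.  Campaigns intended for
  quantitative ΔE_HVR work should be enlarged.
- Lobe and switch residue ranges are conventions, configurable, and
  everything downstream honours the topology's labels rather than
  hard-coded ranges.
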