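# Methods

This note records the models, conventions, and numerical choices behind
`epibind`, and what the synthetic-data experiments do and do not establish.

## Structural data model and IO

Structures are ordered atom lists with author residue numbering; insertion
codes are appended to the residue key.  Units are Å and ns everywhere inside
the package; lengths quoted in nm (e.g. the 0.3 nm clash cutoff) are converted
at the interface (`settings.nm`).  PDB parsing and writing is delegated to
biotite.  Policy decisions layered on top:

- **Altloc**: the conformer with the highest occupancy is kept, ties resolved
  toward the first altloc letter in the file — a deterministic single-conformer
  model.
- **Hydrogens** are read and retained (the H-bond angle needs them) and
  flagged via the element column, falling back to the atom-name leading
  character when the element field is blank.
- **HETATM** records (waters, ions, ligands) are excluded by default; pass
  `include_hetatm=True` to keep them.  Analyses here concern polymer atoms.
- **Trajectories** use a multi-model PDB dialect.  Frame times ride in a
  `REMARK 250 FRAME TIMES (NS):` header; absent that, frames are assumed at
  0, 1, 2, … ns.  All MODEL blocks must list identical atom identities; a
  column-level check rejects reordered frames.  PDB coordinates carry three
  decimals, so round-trips are exact to 1e-3 Å.

Selections are conjunctions of chain, residue-range, and atom-class clauses
(`heavy`, `CA`, `backbone`, `hydrogen`, `all`), resolve in file order, and are
pure functions of (model, expression).  Naming a chain absent from the model
is an error rather than an empty result, catching typos early.

## Predicted-model post-processing

Terminal trimming removes, from each chain end inward, the maximal contiguous
run of residues with pLDDT strictly below the threshold (default 70); a
residue at exactly 70 is kept, interior dips are kept, and a chain entirely
below threshold raises rather than vanishing silently.  The operation is
idempotent.  pLDDT is read from the B-factor column (constant within a
residue; the first atom's value is used), matching the convention of common
prediction pipelines.

Ranking sorts by pTM descending with lexicographic model-id tie-breaks.  The
PAE interface summary is the arithmetic mean over both inter-chain blocks of
the matrix; this is a package convention — upstream tools display PAE but do
not define a scalar interface score.  Score files are JSON with `ptm` and an
optional row-major `pae` matrix in Å.

## Pose geometry

Superposition is the least-squares Kabsch fit via
`scipy.spatial.transform.Rotation.align_vectors`, which enforces a proper
rotation; degenerate inputs (< 3 pairs, collinear fit atoms, judged by the
second singular value) are rejected.  Contact and clash scans consider heavy
atoms only and use strict `<` cutoffs (4.5 Å contacts, 3.0 Å clashes).
Neighbor search uses a k-d tree; correctness is pinned by brute-force
enumeration oracles in the test suite, so the tree is purely a performance
choice.

Competition assessment pairs the shared antigen between the antibody complex
and a reference complex by CA atoms of residues common under author
numbering (an explicit atom-index pairing can override this when numbering
diverges), superposes the reference, and calls competition on ≥ 1 clash pair
between the antibody and competitor selections.  Whether clash marking should
include hydrogens is not standardized; heavy-only is adopted for consistency
with the contact definition.

## Trajectory metrics

- **Subsampling** keeps the first frame at or after each whole multiple of the
  interval (default 1 ns).  **Balancing** then truncates every replica to the
  common minimum frame count so each replica carries equal statistical weight.
- **Fitted RMSD**: each frame is superposed on the fit selection (the antigen;
  CA atoms by default, configurable) against the reference, and the RMSD of
  the calc selection's heavy atoms (the antibody) is evaluated without
  refitting — the displacement of the binder in the antigen frame.
- **Ensemble statistics**: pointwise replica mean and SEM with the n−1
  denominator; SEM is undefined (None) for a single replica.  Plateau values
  average the ensemble mean over the final window (default 200 ns, clipped
  with a warning if longer than the series) and quote the SEM across replica
  window-averages.
- **RMSF** uses residue centers of mass (standard atomic masses) about the
  average structure.  The average structure is produced by a two-pass scheme:
  fit all frames to the first frame, average, re-fit the original frames to
  that average, re-average.  This is a stable two-iteration approximation of
  iterative mean-structure fitting; it is deterministic and, on the synthetic
  ensembles used here (static fit group), exact.
- **Hydrogen bonds**: donors are N/O heavy atoms with ≥ 1 hydrogen within
  1.2 Å (geometric bond inference — no topology file is assumed); acceptors
  are N/O heavy atoms.  A (D, H, A) triple counts when the D–A distance is
  ≤ 3.5 Å (inclusive) and the three-point angle at H is ≥ 150°.  A printed
  band of 150°–210° is the symmetric region |θ − 180°| ≤ 30° of an angle that
  cannot exceed 180°, hence the single lower bound.  Note the two distance
  conventions differ deliberately: contacts are strict (“closer than”),
  H-bond distances inclusive (“at most”).
- **Percent difference** between two ensembles averages within replicas
  first, then across replicas with equal weight, then forms
  100·(⟨a⟩ − ⟨b⟩)/⟨b⟩.  Pooling frames instead would weight longer replicas
  more; the replica-mean convention matches the balanced-frames design.

## Bivalent SPR kinetics

Two interpretations of a two-step kinetic table are implemented:

- **bivalent** (default): one surface capacity Bmax (= `bmax1`); a first
  attachment (ka1 [M⁻¹s⁻¹], kd1) forms R1, a second arm converts R1 to R2
  (ka2 [RU⁻¹s⁻¹], kd2).  Integrated per phase with LSODA, rtol 1e-8,
  atol 1e-10·Bmax; the invariant 0 ≤ R1+R2 ≤ Bmax holds to well within
  1e-6·Bmax.  With ka2, kd2 → 0 the model reduces to the Langmuir single
  site, which supplies two closed-form checks: the association equilibrium
  Bmax·C/(C + kd1/ka1) and pure exp(−kd1·t) dissociation.
- **two_site**: two independent parallel Langmuir sites (ka_i [M⁻¹s⁻¹],
  kd_i, Bmax_i), evaluated in closed form (the per-site ODE is linear), the
  interpretation consistent with a table that prints two Bmax values.  The
  two sites are exchangeable labels; fits should be compared as KD sets.

`ka2` units differ between the models and are carried in the fit result's
unit metadata to prevent silent misuse.  Mass-transport limitation is not
modeled.  Global fitting runs trust-region reflective least squares on log10
parameters inside a box (model-aware defaults; user-suppliable), with seeded
multi-starts: every start gets a cheap screening pass (max 40 residual
evaluations at solver rtol 1e-5), and the best candidate is polished at
ftol = xtol = 1e-10.  Standard errors come from the Gauss–Newton covariance
at the optimum, mapped from log to linear scale by the delta method.  A fit
of all-zero curves is flagged degenerate (Bmax at its lower bound).
Equilibrium constants are always the exact quotient KD = kd/ka;
`validate_printed_affinity` audits a printed (ka, kd, KD) row at the third
significant figure, allowing one unit in the last printed place since the
inputs are themselves rounded.

The bundled reference table for the two anti-PD-L1 clones is reproduced as
published; its 12F1-1 first step (ka1 = 2.08×10¹², kd1 = 6.34×10⁻¹⁴,
KD1 = 3.05×10⁻¹⁶ M) is internally inconsistent — kd/ka evaluates to
3.05×10⁻²⁶ M, ten orders below the printed value, suggesting an exponent typo
in ka1.  The package flags this row; it does not guess a correction.

## Synthetic data: what it emulates and what it does not

The generators stand in for predicted complex models, MD trajectory
ensembles, and instrument sensorgrams, at toy scale and with exactly known
ground truth:

- `make_complex` builds a three-chain complex (antigen A, binder heavy H and
  light L; one CA + one CB proxy heavy atom per residue, 6 Å residue
  spacing with a sinusoidal out-of-line offset so CA sets are never
  collinear).  One binder residue is lowered 4.0–4.3 Å over each requested
  epitope residue; the 6 Å spacing keeps every neighbour outside the 4.5 Å
  cutoff, so the resulting contact map equals the request exactly.
- `make_ensemble` jitters each binder residue rigidly by an isotropic
  Gaussian offset per frame (per-axis σ), antigen static by default.  The
  rigid per-residue displacement makes the residue-COM RMSF expectation σ√3
  exact regardless of atoms per residue.  An optional rigid drift d (Å/ns)
  of the binder makes the antigen-fitted RMSD grow as |d|·t.
- `make_hbond_lattice` places isolated donor–acceptor pairs (donor i with
  acceptor i, 20 Å apart; surplus atoms parked far away) at requested
  distances and D–H⋯A angles, and returns the exact count satisfying the
  criteria.  The hydrogen position for a requested angle is solved by
  bisection, which is monotone in the placement angle.
- `make_sensorgrams` simulates the chosen kinetic model at the emulated
  injection series (2.5, 5, 10 nM; 300 s association + 300 s dissociation at
  1 Hz) and adds seeded Gaussian noise with σ = `noise_frac`·Bmax.

Default kinetics (ka1 = 1.5×10⁶ M⁻¹s⁻¹, kd1 = 10⁻², ka2 = 5×10⁻⁶ RU⁻¹s⁻¹,
kd2 = 2×10⁻³, Bmax = 150 RU) were chosen by an identifiability design rule:
the kd1 decay time (100 s) sits inside the dissociation window, rebinding is
kept secondary (ka2·Bmax ≤ 0.1·kd1), and the second step appears as a slow
tail.  In a rebinding-dominated regime the dissociation phase carries no
kd1 information and no fitter can recover it; parameter-recovery experiments
presuppose identifiable generating conditions.

All randomness flows from `numpy.random.default_rng` seeded through
`SeedSequence([seed, stream])` with fixed stream ids per output class, so a
seed reproduces every output bit-for-bit across platforms.

**Limits.**  The synthetic geometry is not protein-like: no secondary
structure, no sidechain chemistry, unit-like masses (all-carbon proxies), and
fluctuations that are uncorrelated in time and between residues.  Passing
tests therefore establish that the *metrics* are computed correctly (against
closed forms and brute-force oracles), not that any biological conclusion
about a real antibody would be reproduced; real MD ensembles have correlated,
anisotropic motion, and real sensorgrams carry drift, bulk-shift and
mass-transport artefacts that the generators deliberately omit.  Headline
full-scale MD comparisons (multi-microsecond contact and H-bond differences
between clones) require the original trajectories and are out of reach at
desk scale; the suite instead verifies each metric's arithmetic on ground
truth and the comparison statistic's algebra exactly.

## Problem sizes

The test suite and the acceptance script run at deliberately small scale:
100-geometry oracle sweeps for contacts and H-bonds, a 10⁴-frame
single-replica ensemble for RMSF convergence (2% band), 20 noisy replicates
for parameter recovery, and a 2-replica × 6-frame pipeline for the
determinism audit.  These sizes make the whole battery complete in about a
minute and a half while leaving each statistical check comfortably inside its
tolerance.
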