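# Methods

This note records the models the package implements, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the conventions of the
field leave room.

## Pharmacophore model and fit value

A model is an ordered list of features φ, each a sphere with center
**c**ᵩ (Å), tolerance radius *T*ᵩ > 0 (Å), weight *W*ᵩ > 0 and kind ∈
{HBA, HBD, AR}.  A mapped ligand feature at displacement *D*ᵩ from the
center incurs the square error (*D*ᵩ/*T*ᵩ)², and the fit value is

F = Σ_mapped Wᵩ · (1 − (Dᵩ/Tᵩ)²).

Choices:

* **Square error.**  The per-feature penalty is the *squared* relative
  displacement; this is the only exponent for which "sum of square
  errors" is literal and a perfect mapping equals ΣW exactly.
* **Per-feature constraints.**  Each feature carries its own location
  constraint; F sums per-feature terms rather than applying one pooled
  SSE to the whole sum of weights.
* **Outside the sphere = unmapped.**  A feature with D > T contributes
  nothing and can never contribute a negative term; whether the pose as
  a whole survives is governed by `max_omitted` (default 0, the
  strictest reading: every feature must map).
* **Default weights W = 1 and tolerance 1.6 Å** when a model file omits
  them.  Unit weights make F readable as "features matched,
  quality-weighted" (max 6 for the packaged 6-feature model); 1.6 Å is
  a conventional location-constraint radius for pharmacophore spheres.
* The packaged example model has the published feature *composition*
  (3 HBA + 2 HBD + 1 AR) but approximate geometry laid out at a
  plausible catalytic-pocket scale; the original coordinates were never
  published numerically, so the file is flagged
  `"canonical_geometry": false` and must not be read as a faithful
  reproduction.

## Feature perception

Typing is topological (SMARTS), so counts are conformer-independent:
HBD = N/O bearing ≥ 1 hydrogen; HBA = N/O with an available lone pair,
excluding amide and aniline nitrogens, pyrrole-type NH and nitro-group
oxygens; AR = every 5/6-membered aromatic ring, one feature at the ring
centroid.  These minimal standard definitions suit the galloyl-rich
chemistry the screen targets, where activity tracks the number and
placement of phenolic hydroxyls.  Conformer generation is deliberately
out of scope: the package consumes multi-conformer SDF input (or
RDKit-embedded molecules); protonation and tautomers are taken as
given.

## Pose search

For a fixed correspondence, maximising F is equivalent to minimising
Σ wᵩ‖T(xᵩ) − cᵩ‖² with alignment weights wᵩ = Wᵩ/Tᵩ², solved in closed
form by weighted Kabsch superposition (SVD with the determinant
correction, so the rotation is always proper).  This weight choice is
what makes "minimise the weighted sum of square displacements" and
"maximise the fit" the same problem.  Numerical details:

* Correspondences need ≥ 3 pairs (fewer leave the rotation
  underdetermined); collinear or coincident geometries are solved
  best-effort and flagged `well_determined=False` with a warning.
* Pose rejection (any mapped D > T) is applied once, *after* optimal
  alignment; there is no iterative re-mapping, keeping the search
  single-pass and exactly reproducible.
* The correspondence search is exhaustive up to 100 000 assignments per
  conformer; beyond that a greedy beam search (width 50, features in
  descending weight order, partial poses scored by their aligned
  weighted SSD) takes over and the result is flagged `approximate`.
* `rigid` mode scores the first conformer only; `flexible` takes the
  maximum over all supplied conformers.  Ties in the library ranking
  are broken by compound id ascending, making score tables
  deterministic and bit-identical across runs.

## Dose–response

Slopes use ordinary least squares over *all* timepoints of a progress
curve (no linearity-window selection — the assay protocol reads 4
points over 60 min, too few to window).  Inhibition values are never
clamped: values < 0% or > 100% (activation, aggregation artifacts) are
preserved and flagged, because silent clamping hides exactly the
failure modes that make a curve unusable.

The 4PL y = bottom + (top − bottom)/(1 + (IC50/c)^hill) is fitted on
log₁₀ concentration with `scipy.optimize.least_squares`, parameters
(bottom, top, log₁₀IC50, hill), hill bounded to [0.05, 10] and
log₁₀IC50 to the data range ± 3 decades.  Five log-spaced IC50 starting
values spanning the concentration range guard against local minima;
the best-residual solution is kept.  Standard errors are asymptotic
(s²(JᵀJ)⁻¹), with the IC50's SE by the delta method from the log scale;
non-convergence yields a flagged result with NaN SEs rather than an
exception.  Bottom and top may be pinned (e.g. 0/100) to mimic
constrained fits; zero-concentration points are excluded from the
log-domain fit and serve only to define the control slope.

## 1:1 binding kinetics

Association R(t) = Req(1 − e^−(kon·C+koff)t) with
Req = Rmax·C/(C + KD); dissociation decays from R(t_inj) with rate
koff.  The global fit shares (kon, koff, Rmax) across all curves of a
concentration series, with one constant per-curve baseline offset as
the only nuisance term — no mass-transport, drift or bulk-shift terms,
matching a plain 1:1 analysis.  Kinetic parameters are
log-parametrised (positivity by construction, and KD = koff/kon holds
identically in every report); the optimiser is Levenberg–Marquardt
multi-started over a 3×3 log grid kon ∈ {10⁻³,10⁻²,10⁻¹} /(µM·s) ×
koff ∈ {10⁻³,10⁻²,10⁻¹} /s, with log-parameters clipped to ±30 so
exploratory steps stay finite.  Units are µM and seconds throughout;
`kon_per_molar` converts to 1/(M·s).  A single-curve fit is allowed
but flagged ill-conditioned.

## Interaction profiling

Cutoffs (all configurable; conventional geometric criteria, since no
single standard exists): H-bond donor–acceptor heavy atoms ≤ 3.5 Å with
D–H···A ≥ 120° when explicit hydrogens are present (distance-only
otherwise); hydrophobic C/S pairs ≤ 4.5 Å, where "apolar" means no
covalently bonded N/O within 1.8 Å; cation–π ≤ 6.0 Å and anion–π ≤
5.0 Å between group centers and ring centroids; metal–(O/N/S) ≤ 2.8 Å.
Protein aromatic rings and charged groups come from residue templates
(PHE/TYR/TRP/HIS rings, ARG CZ / LYS NZ cations, ASP/GLU carboxylates);
ligand rings from a distance-based bond graph (cycles of length 5–6),
ligand anions from carboxylate/phosphate patterns in the same graph.
Each contact is reported once per atom (or group) pair; a residue-level
summary de-duplicates.  Multi-model PDB is the ensemble format; the
first altloc is kept.

Reproducing any published MD observables is explicitly out of scope:
the underlying trajectories are not deposited, so the detectors and
metrics are validated on synthetic complexes and ensembles with known
ground truth instead.

## Trajectory metrics

RMSD optionally superposes (unweighted proper-rotation Kabsch) before
averaging; RMSF superposes every frame onto the ensemble mean,
refines the mean once from the superposed frames, and measures
fluctuation about it; Rg is the (optionally mass-weighted) second
moment about the center of mass.  Superposition absorbs the six
rigid-body degrees of freedom, which biases RMSF low by a factor
≈ √(1 − 6/3N) — about 2% for N = 50 atoms; tests account for this.

## Synthetic data: what it emulates, what it does not

All generators draw from one explicitly passed seeded generator; no
global RNG state.  Same seed ⇒ byte-identical files, and every
generator returns a manifest recording its truth.

* **Feature libraries** plant perfect hits (model geometry under a
  random rigid motion), near hits (plus isotropic Gaussian jitter,
  default sd 0.3 Å per coordinate, well inside the 1.6 Å tolerance),
  misses (an entire feature kind deleted, hence unscoreable at
  `max_omitted=0`) and random filler.  Pseudo-ligands are labelled
  feature-point sets, deliberately decoupling screening tests from
  perception chemistry; a companion generator embeds genuine small
  molecules (glycerol, phenol, gallic-acid-like scaffolds) for
  end-to-end perception tests.  Neither emulates realistic
  conformational ensembles of large polyphenols.
* **Assay datasets** build linear progress curves (baseline 100 RFU,
  control slope 10 RFU/min, reads at 0/20/40/60 min) whose test-well
  slopes encode 4PL inhibition (bottom 0, top 100), with multiplicative
  Gaussian noise of CV 5% by default — a plain proportional-error model
  with no plate effects, drift or outliers.
* **Sensorgrams** are closed-form 1:1 curves plus additive Gaussian
  noise (default 2 RU on Rmax = 100 RU, 300 s association + 300 s
  dissociation sampled at 2 s) — no mass transport, no regeneration
  artifacts.
* **Toy complexes** place a six-carbon aromatic ring at the origin and
  one protein fragment per planted interaction along well-separated
  directions (π partners on the ring normal, others fanned in-plane at
  45° spacing), each at a distance drawn safely inside its cutoff — or
  0.3 Å beyond it for planted violations — then apply a seeded global
  rigid motion, so detectors must be rigid-motion invariant to
  reproduce the manifest.
* **Ensembles** fluctuate a helix-like backbone with iid Gaussian
  displacements; `per_atom_sd` is the target RMS 3-D displacement
  magnitude (per-coordinate σ = sd/√3), so long-ensemble RMSF
  converges to it directly.  Optional linear drift of an atom slice
  emulates a mobile subdomain.

Because the noise models are idealised, passing recovery tests shows
the *estimators* are correct and well-calibrated under their stated
assumptions; it does not certify robustness to the systematic errors
of real plates, chips or force fields.

## Benchmark problem sizes

The recovery benchmarks (`scripts/acceptance.py` and the validation
suite) use 100 seeded replicates per planted value; IC50 studies use 8
log-spaced concentrations from 0.3 to 300 µM (ratio 10^(3/7) ≈ 2.7,
i.e. near-three-fold steps spanning exactly that range) in triplicate;
KD studies use each analyte's concentration series (6.25–100 µM,
25–200 µM, 0.0625–1 µM) with kon = 0.01 /(µM·s) and sensorgrams
sampled at 2 s.  Medians over replicates are reported, as the IC50 and
KD sampling distributions are right-skewed on the natural scale.

## Known limitations

* No directional pharmacophore constraints (H-bond projected points,
  ring normals), excluded volumes, or feature kinds beyond HBA/HBD/AR.
* No enzyme-mechanism fitting (Ki, modality), assay-QC statistics or
  plate normalisation.
* No bivalent/heterogeneous binding models or steady-state-only
  affinity fits.
* π–π stacking and π–sulfur contacts are not typed; ligand formal
  charges are not inferred from plain PDB files, so ligand-side
  cation–π detection requires charge records.
* The greedy beam fallback is heuristic; results that pass through it
  are flagged and excluded from oracle-equivalence guarantees.
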