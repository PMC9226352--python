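# Methods

## Data model

A structure model carries one score per residue — pLDDT in [0, 100] for a
predicted model (read from the Cα B-factor field, the AlphaFold2 file
convention) or a crystallographic B-factor in Å² — with original chain and
resSeq labels retained while all internal arrays are 0-based and contiguous,
so numbering gaps and insertion codes never reach the math. Insertion-coded
residues are distinct positions in file order; the first altLoc is kept.
PAE matrices are accepted in both AlphaFold-DB JSON dialects (flat
`residue1`/`residue2`/`distance` triplets with 1-based indices, or a nested
list under `predicted_aligned_error`/`pae`); both must produce identical
matrices, and `max_pae` falls back to the matrix maximum when the file
declares none. Only PDB is supported for structures and ensembles (multi-model
PDB for trajectories); binary trajectory formats can be adapted to the same
`Ensemble` contract externally.

## Superposition and RMSF

Rigid fits are least-squares (Kabsch via SVD), restricted to proper
rotations: in the degenerate reflection case the smallest singular direction
is sign-flipped. The fit set is always the Cα atoms of the fit region, also
under the conventional "all-atom" protocol label — Cα-only fitting is robust
to side-chain noise and keeps RMSF, DV and the fit mutually consistent.
Fewer than three or collinear fit points raise a degenerate-fit error.

RMSF uses an iteratively refined mean reference: all frames are fitted to
frame 0, a mean structure is computed, frames are refitted to the mean and
the mean recomputed — exactly two iterations, fixed, for determinism. RMSF
is reported on Cα positions by default (option: mean over backbone heavy
atoms per residue).

**Domain-specific protocol.** For hinged multi-domain systems a global fit
splits the interdomain motion across both domains and inflates every
residue's apparent fluctuation. The domain-specific protocol fits frames on
one segment's residues at a time, reads each residue's RMSF from its own
segment's fit, and assigns declared linker residues the arithmetic mean of
their RMSF under the two flanking segments' fits. Residues covered by no
segment join the nearest segment (termini join the adjacent one); with more
than two domains each linker uses its nearest flanking pair. A
single-segment partition reproduces the global protocol identically.

**Gauge-noise correction (`debias=True`).** A rigid fit estimates 6
parameters from noisy coordinates, so every frame's deviation field is the
true displacement projected onto the orthogonal complement of the six
rigid-body modes: other residues' fluctuations leak into each residue's
apparent RMSF. The effect is largest for stiff residues at the ends of
extended geometries (long lever arms): on a 100-residue extended chain with
per-coordinate σ from 0.2 to 2.0 Å the stiffest terminal residue's plain
RMSF is inflated ~28%, and an inverse-variance weighted fit instead
*under*-estimates it (~8%) because a dominant residue absorbs its own
fluctuation into the fit. At first order the leakage operator is known in
closed form — with rigid-mode basis U and per-residue variances s,
E[observed variance] = 3s_i − 2s_i·tr(G_i) + tr(M⁻¹S M⁻¹UᵢᵀUᵢ), where
M = UᵀU, G_i = Uᵢ M⁻¹Uᵢᵀ, S = Σ_j s_j UⱼᵀUⱼ — and is inverted by a
12-step fixed point (the leakage terms are O(1/R), so convergence is
immediate). The corrected estimator recovers the generator's σ√3 to under
2% at F = 10⁴ where the plain estimator errs by 28%. The default remains
the conventional uncorrected RMSF, which is what trajectory-analysis
packages report and what the two-frame contract (a residue jumping 2d
across frames has RMSF d) pins down.

## Distance variation, DCCM, PCA

`DV(x, y)` is the interquartile range, over frames, of the Cα–Cα distance
between residues x and y. Quantiles interpolate linearly between order
statistics with p(k) = (k−1)/(n−1) — the common statistical-software
default — recorded on the matrix as `quantile_method`. The IQR damps rare
extreme separations; distances are rigid-motion invariants, so DV needs no
superposition and is exactly symmetric with a zero diagonal. All frames are
used by default (CLI `--stride` subsamples long trajectories); distances
are computed in residue blocks so the F×R×R tensor is never materialised.

DCCM entries are ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) on Cα deviations
after the global fit (scalar dot-product normalisation, the convention of
the standard trajectory-analysis tools). Zero-variance residues have
undefined correlations; their rows/columns are set to 0 with a warning, and
NaNs never propagate.

PCA scales each Cartesian coordinate by √mass, removes the mean, and
diagonalises the 1/(F−1) covariance; eigenvalues (Å²·amu) are descending,
modes orthonormal, and the eigenvalue sum equals the covariance trace.
Frames are pre-fitted with the global protocol; hydrogens are excluded by
default. PC animations map a mode back to unweighted Cartesian
displacements (÷√mass) and sweep mean ± amplitude in `n_steps` frames,
writable as multi-model PDB.

## Scores and concordance

The AF2-score uses the profile's own pLDDT extrema, not the theoretical
0/100 range — this matches the unit-range normalised profiles the score is
compared against; the fixed range is an option. Constant profiles return
zeros with a warning rather than an error, so batch pipelines survive
pathological inputs. B = (8π²/3)·RMSF² bridges to crystallographic
B-factors; √B (optionally min–max normalised) is the profile compared with
RMSF. The disorder summary counts residues strictly below a pLDDT
threshold (default 50) and reports the profile median and IQR.

Per-residue concordance is the Pearson correlation with a two-sided t-test
p-value plus an OLS slope/intercept. p-values are never thresholded by the
library and are floored at 1e-300 (values below double-precision resolution
would otherwise print as 0). Correlations against constant vectors raise an
error rather than return NaN. Matrix-level concordance symmetrises the PAE
as the mean of transpose pairs (the DV matrix is symmetric while the PAE is
not) and correlates strict upper triangles — no double counting, and the
structurally zero DV diagonal never enters; correlating the raw asymmetric
upper triangle is an option. The near-diagonal signature is the mean of
entries at sequence separation 1..window (default 8, both triangles):
folded chains keep adjacent residues at nearly fixed separations, so high
values flag disorder. Matrices smaller than the window fall back to all
off-diagonal entries with a warning. Cross-protein aggregate regression
takes per-protein profile means with the flexibility measure as response.

## Synthetic generators

The generators provide the three regimes the analysis must distinguish,
each with exact ground truth and one seeded `numpy` generator per call (no
global state; identical seeds give bitwise-identical ensembles).

* **Gaussian chain** — residue i fluctuates isotropically with
  per-coordinate σ_i about an extended trace with exact 3.8 Å consecutive
  Cα spacing; expected RMSF is σ_i√3. The trace zigzags (±20° alternating
  bond directions) rather than lying on a line: a strictly straight trace
  is collinear and makes superposition degenerate.
* **Two-domain hinge** — two internally rigid *compact* serpentine blocks
  (grid-folded chains, exact 3.8 Å spacing) joined by a straight linker;
  each frame rotates linker+domain 2 about the first linker residue's Cα,
  around z, by θ ~ Normal(0, hinge_angle_std). The interdomain
  centre-of-mass distance has a Rodrigues closed form in θ, reproduced by
  the pipeline to 1e-8. Compactness matters: rod-shaped domains are nearly
  degenerate under rotation about their long axis, which lets the global
  fit spin frames almost freely about that axis and scramble the mode
  spectrum (measured PC1 fraction 0.73 for helical rods vs 0.98 for compact
  blocks at the same hinge statistics). At hinge_angle_std = 15° the
  quadratic (1−cos θ) term carries ~σ_θ²/2 ≈ 3% of the variance, so PC1
  should hold ≳95%; the locked test threshold is 0.9.
* **Disordered chain** — an ideal freely-jointed chain redrawn
  independently each frame (uniform random 3.8 Å steps). Adjacent distances
  are exactly constant, so DV(i, i+1) = 0 by construction and the disorder
  signature must use window ≥ 2 — at separation ≥ 2 the DV is large even
  between near neighbours, the disordered fingerprint.

Defaults represent the study conditions: gaussian σ ∈ [0.2, 2.0] Å
(terminus-to-core flexibility span), hinge domains of 60 residues with an
8-residue linker and 15° angle std (large-amplitude but hinge-like), 3.8 Å
virtual bonds throughout, uniform carbon masses (Cα-only geometry makes
mass-weighted PCA uniform-weighted here).

The **pLDDT emulator** draws pLDDT_i = clip(60 − a(σ_i − σ̄) + ε, 0, 100)
with the gain solved so the population correlation with σ equals −coupling:
a = coupling·noise_std/(sd(σ)√(1−coupling²)); defaults coupling 0.9,
noise 5 pLDDT units (strong but imperfect anticorrelation, as observed for
well-aligned globular proteins), baseline 60 keeping clipping negligible.
The **PAE emulator** draws PAE = clip(gain·DV + offset + ε, 0, max_pae)
with independent noise per ordered pair, producing realistic asymmetry;
defaults gain 1.75 and offset 0.25 Å (PAE maps run roughly twice as large
as DV since an IQR is about half a range), noise 1 Å, max_pae 31.75 Å (the
AlphaFold-DB ceiling). The recorded truth is the expected upper-triangle
correlation after symmetrisation (noise variance halves).

What the generators deliberately omit: temporal autocorrelation (frames are
independent — DV and RMSF estimators do not need correlated sampling, but
convergence-rate conclusions would not transfer to real MD), side chains,
solvent and any force field. Passing tests therefore demonstrate estimator
correctness and pipeline integrity on ensembles with known truth, not
agreement with physical simulation.

## Numerical choices and degenerate inputs

* Quantiles: linear interpolation everywhere (one rule for IQR, DV and
  disorder summaries).
* Kabsch reflection tie-break: force det = +1 by flipping the smallest
  singular direction.
* OLS via `lstsq` on the [x, 1] design; constant x is an error, constant y
  a legal zero slope.
* DCCM/PCA covariance: 1/F for DCCM normalisation cancels in the quotient;
  PCA uses the 1/(F−1) estimator.
* Constant score profiles: zeros plus a warning (never NaN, never a crash).
* PAE v1 triplets must cover every ordered pair; incomplete covers are
  format errors, not silently zero-filled.
* Heatmap colour scale: 256 bins, dark green = lowest to white = highest;
  explicit break lists must be strictly increasing and are honoured exactly
  via piecewise bins.

## Problem sizes

Tests and the acceptance script run the generators at R = 30–200 residues
and F = 80–10000 frames: large enough that sampling intervals (Fisher-z for
correlations, √F scaling for moment estimators) are tight around the
ground truth, small enough to run on a laptop in seconds. The RMSF-recovery
check uses the full R = 100, F = 10⁴ condition; hinge analyses use F = 5000.

## Known limitations

* No mmCIF input; no binary trajectory readers in the core.
* Sequence/structure correspondence is by index: model and trajectory must
  list the same residues in the same order, or an alignment error is raised.
* The gauge-noise correction assumes isotropic per-residue fluctuations and
  first-order (small-angle) leakage; it is exposed for Cα profiles only.
* p-values assume independent observations; matrix-level correlations over
  residue pairs share residues, so their printed p-values are optimistic —
  they are reported, never interpreted, by the library.
* External disorder predictions (e.g. sequence-based disorder scores) are
  ingested as a TSV column, never computed.
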