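# Methods

## The model

Ion-mobility mass spectrometry measures a rotationally averaged collision
cross-section (CCS, Å²): the effective area a protein ion presents to a
buffer gas while drifting through it. Under the projection approximation
(PA), the CCS is the mean projected 2D area of the molecule over uniformly
random orientations, with each atom treated as a hard disk of radius
r_atom + r_gas; scattering, long-range interactions and concavity effects
are ignored. PA is known to be accurate to a few percent for compact
globular proteins, which is the regime this package targets.

### Rough-circular-shapes area estimator

The expensive part of PA is the per-orientation area. This package
rasterizes each projection on a grid of 1 Å² cells and, for every atom,
fills nine cells: the cell under the projected atom center and the eight
cells under the points at distance r every 45° around it. The projection
area is the filled-cell count times the cell area; the CCS is

    CCS = Σ_i (A_i^{xy} + A_i^{xz} + A_i^{yz}) / N,   N = 3R

over R random rotations, three orthogonal projections each. The atom stamp
deliberately does **not** fill the disk interior: in a protein-density atom
cloud neighbouring stamps tile the interior anyway, and the sparse stamp
keeps the fill O(9·n_atoms) per projection. The estimator is therefore
*only* valid in the dense regime — a single isolated carbon in helium
yields exactly 9 Å² against a true disk area of π·2.91² ≈ 26.6 Å² (this is
asserted in the tests as a feature, not a bug).

Radii: 1.91 Å for C/N/O/S/P, 1.21 Å for H, plus the buffer-gas radius
(1.0 Å helium, 1.82 Å nitrogen). Elements outside that set fall back to
1.91 Å with a warning. Hydrogens are used when present in the input but are
never built; reported accuracies against experiment assume pre-protonated
structures, and a `--heavy-only` flag drops hydrogens instead.

Numerical conventions (the cartoon leaves them open; these are this
package's choices): cells are half-open, a point (u,v) belongs to cell
(⌊u−o_u⌋, ⌊v−o_v⌋); circumference points are floored into cells, not
rounded (a sub-1% effect at 1 Å cells); the grid is rebuilt per rotation
and plane from the projected extremes plus a 5 Å margin, which exceeds the
largest combined radius (3.73 Å) so stamps cannot escape — asserted at
grid construction. Rotation matrices are drawn uniformly over SO(3) via
quaternion sampling from a seeded generator; the structure is rotated about
its centroid (areas are translation invariant, the centroid only pins
reproducibility). Repeated runs derive child seeds by seed-sequence
spawning, so they are independent but exactly replayable.

Defaults: R = 300 rotations (run-to-run CCS spread of order 1 Å² for small
proteins; convergence is monitored with `convergence_profile`, whose spread
shrinks roughly as 1/√R), cell side 1 Å, pad 5 Å, buffer gas nitrogen (the
more common modern choice — every CLI surface states it explicitly since
both gases are supported on equal footing).

## The restraint score

Given a measured CCS, each candidate model is penalized by its absolute
CCS deviation ΔCCS through a cubic fade:

    penalty = 0                         ΔCCS < LB
            = 100·(2x³ − 3x² + 1)       LB < ΔCCS < UB,  x = −(ΔCCS−UB)/(UB−LB)
            = 100                       ΔCCS > UB

with LB = 10 Å², UB = 100 Å², maximum 100 score units. At the exact bounds
the cubic agrees with both flat branches (x = 1 gives 0, x = 0 gives 100),
so assigning the boundary points to the fade branch is value-free; the
function is continuous and monotone. The combined score is simply
base_score + penalty, where the base score is an externally computed
all-atom energy (lower is better); this package consumes such scores from
Rosetta-style score files or CSV and never computes them.

Two structural consequences of this parameterization, both exercised in
the tests: when every model's ΔCCS exceeds UB the penalty is a constant
shift and the restrained ranking collapses to the base ranking; and the
restraint can only reorder models whose ΔCCS lies inside the fade band.
For a compact globule dCCS/dRMSD is of order 100–170 Å²/Å (expansion-
driven), so with UB = 100 Å² the informative window is roughly the first
Ångström of RMSD — the synthetic rescoring experiment spans 0.3–3 Å for
exactly this reason.

### Confidence metric

The confidence score of a prediction run is the mean combined score of the
100 best-scoring models divided by the sequence length (distinct retained
residues, not a SEQRES length — decoys are full-length in the intended
workflow). Values strictly below −2.54 score units per residue flag a
high-confidence prediction. With fewer than 100 models the mean is over
all of them, with a warning. The 0–1 rescaling (`scaled_confidence`) is a
presentation convenience whose anchoring — threshold ↦ 0.5, span 2.0 score
units/residue, clamped — is this package's own convention, configurable
and excluded from any numeric claim.

### CCS uncertainty injection

`perturb_ccs` supports two modes: multiplicative uniform noise of ±p%
(a deliberately simple measurement-error model) and deterministic
reduction by p% (emulating gas-phase compaction of the target value).
The uniform-multiplicative choice is a documented modeling decision of
this package, not a measured error distribution.

## Evaluation metrics

* **RMSD**: Cα root-mean-square deviation after least-squares rigid
  superposition (Kabsch). Residues pair by ordinal — decoys and natives
  share a sequence; no alignment search is attempted (documented
  limitation for cross-sequence use).
* **TM-Score**: (1/L)·Σ 1/(1+(d_i/d0)²) maximized over superpositions,
  d0 = 1.24(L−15)^{1/3} − 1.8 floored at 0.5 Å (also used for L < 16).
  The maximization uses the standard iterative heuristic (fragment-seeded
  rigid fits refined on the residues currently within the cutoff). Exact
  agreement with the reference program is not promised; the identity limit
  (=1), the random-pair limit (<0.17) and hand-computable cases are
  asserted instead.
* **Radius of gyration**: unweighted RMS distance of heavy atoms from
  their centroid (mass weighting is an opt-in flag; the unweighted form is
  the package's convention). `rg_rank` orders an ensemble most-compact
  first as the compactness-only proxy score.
* **P_near**: Σ exp(−rmsd²/λ²)·exp(−E/kT) / Σ exp(−E/kT) with kT = 10
  score units and λ = 1 Å, computed in log space after shifting energies
  by their minimum; ranges from 0 (no funnel) to 1 (perfect funnel).
* **Neighbor count**: residues within 10 Å of a residue's representative
  atom (Cβ, Cα for glycine); the sphere radius is configurable since the
  reference implementation's defaults are not published. "Surface
  residues" are the lowest-X% neighbor counts (X = 5–20 typical).

## Synthetic fixtures and what they do (and do not) show

`gen_globule` builds pseudo-proteins: a self-avoiding Cα walk (3.8 Å
steps, backtracking on dead ends) confined to a sphere of radius
3.0·n^{1/3} Å, each residue decorated with 7 satellite heavy atoms 1.5–2.5 Å
from its Cα, all atoms pairwise ≥ 1.5 Å. Eight heavy atoms per residue is
the mean for real amino acids and yields ~113 Å³ per residue
(≈ 0.07 heavy atoms/Å³), the density regime in which the 9-point stamp is
valid — with 5 atoms per residue the same envelope is unphysically sparse
and the stamp's deviation from the exact estimator triples. The walk fills
its sphere roughly uniformly (rg ≈ 0.72–0.80 of the packing radius,
uniform-ball limit 0.775), which the tests freeze as a regression band of
[0.6, 1.0]×3.0·n^{1/3}.

These globules have protein-like density but no secondary structure,
side-chain chemistry, or concave surface features; passing the oracle-
equivalence tests on them shows the area estimator is unbiased in its
intended density regime, not that predicted CCS matches experiment for
real proteins (that comparison requires real, protonated structures — see
`scripts/fullscale_benchmark.py`).

`gen_decoys` perturbs a native by global expansion plus small jitter, so
RMSD, Rg and CCS grow together, and assigns synthetic base scores
funnel_slope·RMSD + Gaussian noise. A negative slope manufactures an
anti-funneled landscape with known ground truth — the simplest setting in
which restraint-driven rescue of model selection can be demonstrated and
measured.

`union_disk_area_oracle` is the independent reference for projection
areas: a fine sub-grid count (0.05 Å cells, default) or Monte Carlo
rejection sampling with a reported standard error; the two cross-check
each other and, in the test suite, an exact polygon-union area.
`pa_ccs_oracle` runs the full CCS protocol with these exact areas and
shares the rotation stream with the rough-stamp path (verified by a
rotation fingerprint), so rough-vs-full differences isolate the area
estimator. On the frozen 50-globule set (50–400 residues) the rough stamp
deviates at most ~1.8% (mean ~0.7%) from the exact estimator with
R² > 0.999 — computed fresh on every test run, never stored.

## Problem sizes in the test suite

The suite runs desk-scale versions of the large benchmarks: 50 globules of
50–400 residues at R = 3 shared rotations for oracle equivalence (shared
streams make the comparison exact per rotation, so small R does not weaken
it), 10 globules × 20 repeats at R ∈ {100, 400} for convergence, and a
50-decoy ensemble for rescoring. These sizes keep the whole suite in the
minutes range on one CPU while preserving every qualitative contract.

## Known limitations

* PA itself underestimates CCS for large or concave ions compared to
  trajectory-method calculations; nothing here corrects for that.
* No hydrogen building: un-protonated inputs will underestimate CCS.
* Nitrogen's larger combined radii widen the unfilled annulus between an
  atom's center cell and its 9-point ring, so rough-vs-full-disk agreement
  is a few percent looser in nitrogen than in helium at equal density.
* First MODEL only, altloc by max occupancy, HETATM off by default, waters
  always dropped; mmCIF is not read.
* Charge-state effects, gas polarizability and temperature dependence are
  out of scope.
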