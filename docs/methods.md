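# Methods

## The scientific question and the quantities computed

Receptors from unrelated families sometimes bind the same small molecule.
The pipeline in this package quantifies *pocket congruence* — the idea that
what such receptors share is not global sequence or fold similarity but
local properties of their binding pockets — and tests it as a battery of
correlations against a pocket-similarity score (PS-score) supplied by an
external pocket-alignment tool.

For a compared pocket pair, one analysis record carries:

* **PS-score** in [0, 1] — consumed from pocket-comparison reports, never
  computed here.
* **|Δaffinity|** (kcal/mol) — the absolute difference of the best docking
  affinities of the same ligand in the two pockets.  Per docking log, the
  retained mode is the one with the most negative affinity; ties break to
  the lowest mode index.
* **Conformer RMSD** (Å) — deviation of the two docked ligand conformers
  after optimal rigid superposition (Kabsch, proper rotations only so
  chirality is preserved) of atoms paired by identical atom name.  ≥3
  matched atoms are required; collinear inputs are computed with a warning.
* **Shared contacts** — residues with any heavy atom within 5 Å of any
  ligand heavy atom count as contacting; because the two proteins differ,
  "same residue" means same amino-acid type, counted as the multiset
  intersection of the two contact sets' type multisets (each residue used
  once).  The 5 Å cutoff is the package default and is overridable.
* **MS-WHIM distance D** — each pocket is reduced to the component-wise
  arithmetic mean of the per-residue MS-WHIM triples (three principal
  components of molecular electrostatic-potential surface properties,
  transcribed from Zaliani & Gancia 1999); D is the Chebyshev (L∞)
  distance between the two pocket points.  The descriptor is
  composition-only: two pockets with the same residue-type multiset are at
  D = 0 regardless of geometry.  Mean aggregation is count-weighted over
  residues; a sum aggregate exists behind a switch for sensitivity
  analysis.  Non-standard residues are excluded, not imputed.
* **Overlap sum** in [0, 2] — per pocket, the fraction of its residue
  positions lying inside the region of its protein found structurally
  similar to the partner protein, `S = N(aaP ∩ aaPK) / N(aaPK)`; scores
  from the flexible and rigid alignment modes are averaged, and the two
  per-pocket means of a pair are summed.  The score is normalized by pocket
  size (asymmetric by design) and intersects on author-numbering position
  triples (chain, residue number, insertion code); amino-acid type plays no
  role.  When only one alignment mode is available the mean degrades to
  that mode's score with a warning rather than treating the missing mode as
  zero.  The raw [0, 2] sum is reported; normalization is left to callers.

The battery computes Pearson correlations of PS-score against each field,
pooled and per ligand, with two-sided p-values from the t-transform with
n − 2 degrees of freedom.  The congruence hypothesis predicts negative signs
for the dissimilarity measures (|Δaffinity|, conformer RMSD, D) and positive
signs for shared contacts and overlap.  Missing fields are excluded
pairwise per association (not listwise), so per-association n's differ.
Raw p-values are the primary output; a Benjamini–Hochberg `q_bh` column is
appended as a clearly labeled extension.  Sample (n − 1) standard deviations
are used throughout.  A paired t-test (df = n − 1) on deposited-complex vs
re-docked conformer RMSDs serves as the docking-reliability control.

A shipped table of 32 receptor-pair structural comparisons (flexible/rigid
alignment RMSDs and sequence-similarity percentages) supports the
low-similarity claim: the fraction of pairs with both similarities below a
threshold (default 30%) is computed with strict `<` by default and `≤`
behind a flag — one shipped row sits exactly at 30%, which is why both
conventions are exposed (24/32 = 0.75 strict, 25/32 = 0.78125 inclusive).

## Input formats and addressing

Residues are addressed everywhere by the author triple (chain id, residue
number, insertion code), never by sequential index, so pocket lists and
alignment regions produced by different tools agree on addressing.
Coordinates travel as PDB files parsed with gemmi: the first altloc
conformer is kept, waters always dropped, hydrogens dropped, and the chain
with the most residues is the default comparison subject.  Pocket lists and
region reports use a small documented tabular dialect defined by this
package; PS reports and docking logs are tolerant line-scanners keyed on
labeled fields ("PS-score", "RMSD", the mode table) because the upstream
tools' formats are versioned and under-specified.  How a pocket-prediction
server's output is converted into a residue list is the caller's choice;
any residue list is accepted.

## Synthetic data: what it emulates and what it does not

No real pocket/docking dataset ships with the package, so a generator
produces all inputs with known ground truth at two levels.

**Record level.**  A latent pocket similarity `s ~ Uniform(0.11, 0.90)` (a
span matching the range of PS-scores the pipeline is meant to ingest) is
reported verbatim as the PS-score and drives every field.  Continuous
fields are `α + β·s + N(0, σ²)` with σ the per-field noise scale
(0.8 kcal/mol for |Δaffinity|, 0.6 Å for RMSD, 0.15 for D, 0.2 for the
overlap sum) and β solved in closed form so the population Pearson
correlation with `s` equals the planted value exactly; α anchors the
smallest conditional mean at 3.5σ so truncation at physical zero carries
negligible (<3·10⁻⁴) mass.  Shared contacts are Binomial(10, p(s)) with
p linear in `s`, whose slope is likewise solved in closed form (exact
because E[X|s] stays linear in s); an infeasible planted value raises an
error stating the feasible range.  Default planted correlations are
−0.5 (|Δaffinity|), −0.3 (RMSD), +0.4 (contacts), −0.4 (D), +0.3 (overlap)
at n = 2000 — moderate effects with the congruence sign pattern.  Affinity
pairs are placed in the docking-typical −12…−4 kcal/mol range and split so
|affinity_a − affinity_b| equals the generated gap.  The eight ligand
labels are cycled so per-ligand summaries are exercised.

**Structure level.**  Each toy receptor is a smooth helical trace (five
heavy atoms per residue) — not a physical fold; the geometry only needs to
exercise distance and superposition code.  Pockets are the k nearest
residues around chosen centers; similar regions are random residue ranges;
PS-scores are drawn uniformly (independent of everything else, so the
bundle's battery is a null dataset by construction); docking logs carry six
modes with sorted affinities, and the retained pose is a recorded rigid
motion of the deposited pose plus optional Gaussian jitter.  All
coordinates are rounded to 3 decimals so PDB fixed-column round trips are
bit-exact, and the retained-pose rotation is an axis permutation/flip so
the rigid relationship itself survives the file format exactly — with zero
jitter the pipeline's superposition RMSD is 0 to ~1e-15.  Ground truth
(exact overlap scores, exact 5 Å contact sets computed by a direct
all-pairs scan, pose transforms, expected jitter RMSD
σ·√(3(n−2)/n)) is stored in truth CSVs beside the bundle.  Identical
configs produce byte-identical bundles.

Passing tests on these data show that the arithmetic, file handling and
statistical machinery are correct and deterministic; they do not show that
real pockets behave this way — real PS-scores, affinities and contacts are
produced by external tools with their own biases, and the latent
one-factor structure of the record generator is an idealization of the
congruence narrative, not a physical model.

## Numerical and design choices

* Superposition residuals are measured explicitly after the fitted
  rotation; the closed-form residual sum of the underlying solver loses
  ~1e-8 of precision to cancellation on near-exact rigid copies.
* Overlap and descriptor computations are plain ratios and means; no
  smoothing or pseudo-counts anywhere.
* `pearson` refuses constant vectors and n < 3 by name rather than
  returning NaN; the paired t-test returns t = 0, p = 1 for identical
  vectors and raises when nonzero differences have zero variance.
* The pipeline analyzes exactly the pocket pairs listed in the PS reports;
  a flag cross-products pocket files when no report exists (PS then flagged
  missing).  No pocket filtering is applied before comparison.
* Reports are deterministic: fixed float formats, sorted iteration, and a
  versioned CSV + JSON-lines schema.  Re-running on identical inputs
  reproduces identical bytes.
* Contact counting collapses any interaction-type distinction (hydrogen
  bond vs hydrophobic) into the single 5 Å distance criterion; bond-type
  classification is out of scope, and counts may therefore exceed those of
  a tool that restricts to hydrogen bonds.

## Problem sizes

Default verification sizes — 1,000 random set pairs for the overlap oracle,
500 descriptor triples, 100 contact instances, 20 conformer pairs against a
rotation-grid oracle, 20 seeds × 2,000 records for correlation recovery,
and an 8-receptor × 3-pocket end-to-end bundle (252 compared pairs) — were
chosen so each check is statistically meaningful while the whole suite runs
in well under a minute on one core.

## Known limitations

* The MS-WHIM pocket descriptor ignores geometry entirely; it is a
  composition summary, and duplicate residues are count-weighted (flagged
  for users who expect type-set weighting).
* RMSD atom pairing requires the two poses to be the same chemical ligand
  with consistent atom names; no graph-isomorphism matching is attempted.
* mmCIF, NMR multi-model files and biological-assembly expansion are not
  supported; docking, pocket prediction and structural alignment themselves
  are never invoked — their outputs are consumed as inputs.
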