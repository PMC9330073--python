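# Methods

## The assessment model

The package treats one prediction run as an ensemble of ranked models (five
by default, ranked by mean pLDDT over all residues) sharing chain
composition and residue numbering.  Reliability is judged by three
independent signals:

1. **Pose consensus.**  Two models "agree" when, after superposing their
   receptor Cα atoms (Kabsch, uniform weights, no outlier-rejection
   cycles), the ligand-fragment Cα RMSD — measured in place, with no second
   fit — falls below a threshold.  We use 4.0 Å: correctly predicted poses
   in this problem class sit near 1 Å while reversed or relocated poses sit
   tens of Å away, so the verdict is insensitive to the exact value (it is
   config-exposed regardless).  Clustering is single-linkage (connected
   components of the thresholded pairwise graph) because the underlying
   notion is pairwise resemblance, not distance to a centroid.  With n
   models, `converged` requires a cluster of ⌈0.6 n⌉, `failed` means the
   largest cluster is under ⌈0.5 n⌉.  The pairwise matrix is symmetrized by
   the maximum of the two anchoring directions (they differ when the
   receptors differ), the conservative choice.

2. **Confidence localization.**  For each ligand residue we record pLDDT
   (Cα B-factor) and the minimum and mean symmetrized cross-chain PAE
   (PAE is asymmetric; entries (i,j) and (j,i) are averaged, making the
   profile invariant to transposition).  A residue is bound-like when the
   smoothed (centered moving mean, window 5) pLDDT is ≥ 70 and the smoothed
   minimum cross-PAE is ≤ 10 Å; runs of ≥ 6 residues are candidate
   intervals, merged across models at ≥ 50% reciprocal overlap and kept at
   ≥ 60% ensemble support.  These thresholds are calibrated, not measured:
   they reproduce the qualitative verdict pattern (full-consensus and
   majority ensembles yield a call, 2-of-5 ensembles do not) and are all
   config-exposed.  Mean smoothing makes the interval endpoints soft by
   about half a window (±2 residues) when the block values sit near the
   thresholds; the planted-region recovery guarantee is therefore stated as
   ±5 residues.

3. **Interface plausibility.**  Buried area, contact maps and residue
   classes of the consensus representative, and a CAD comparison when a
   reference structure exists.

### Interface machinery

SASA uses Shrake–Rupley quadrature with a fixed golden-spiral lattice of
960 points per atom (no RNG; deterministic and monotonically refinable —
the 10 000-point refinement agrees within 3% on the toy complex).  Atomic
radii are a fixed per-element van der Waals table (C 1.70, N 1.55, O 1.52,
S 1.80 Å, …); hydrogens are ignored everywhere, unknown elements fall back
to carbon with a warning.  Probe radius 1.4 Å.

Buried area is reported per side — (SASA_receptor + SASA_ligand −
SASA_complex)/2 — the common single-interface convention; the total is also
emitted.

Residue–residue contact areas are estimated by burial apportionment rather
than Voronoi tessellation: each atom's burial (its SASA alone minus in
complex) is shared among partner-side residues having any atom within
6.5 Å, weighted by 1/d² of the nearest-atom distance, and the (i,j) entry
accumulates burial from both sides.  The 6.5 Å reach covers the maximal
occlusion distance r_i + r_j + 2·probe (≈ 6.2 Å for carbon), which is what
makes the conservation identity Σ contact areas ≈ total SASA loss hold to
the ~5% the apportionment itself costs.  Entries under 0.1 Å² are dropped.
Absolute contact areas differ from Voronoi-based estimators, so CAD scores
from this implementation should be compared by rank, not value, against
other tools.

The CAD score uses the bounded-difference variant,
`1 − min(1, Σ|T − min(M, 2T)| / ΣT)` over target contacts, which stays in
[0, 1] under gross over-prediction.  A target with an empty interface is an
error, never a score of 0.

Interface classes are geometric: salt bridge = basic side-chain N
(Arg/Lys/His; His is treated as potentially protonated, and the report says
so) within 4.0 Å of an acidic side-chain O (Asp/Glu), including
chain-terminal amine/carboxylate; hydrogen bond = any cross-interface N/O
pair within 3.5 Å; hydrophobic = C–C within 4.5 Å between apolar side-chain
moieties (Ala, Val, Leu, Ile, Met, Phe, Trp, Pro side chains and the Tyr
ring).  No hydrogen placement is attempted.

### Stoichiometry assessment

Runs made at different declared copy numbers are compared by their
consensus verdicts.  Exactly one converged ratio → preferred; several →
prefer the larger buried interface of the cluster representatives, with a
warning (and "undetermined") when areas agree within 5%; none →
undetermined.

## The one-site ITC model

Constant-volume perfusion convention: injection volume v displaces cell
content, so after injection i the totals are `M_t = M₀ dⁱ`,
`L_t = L_s (1 − dⁱ)` with `d = 1 − v/V₀`.  The bound concentration is the
smaller root of the mass-action quadratic, evaluated in the numerically
stable form `2·N·M_t·L_t / (b + √(b² − 4 N M_t L_t))` to avoid cancellation
when [ML] is tiny.  Per-injection heat (µcal) is
`ΔH·V₀·([ML]_i − [ML]_{i−1}·d) + q_dil`; normalized heats divide by moles
injected (kcal/mol of injectant).  Fitting is `scipy.optimize.least_squares`
on normalized heats with K_d on a log₁₀ scale (positivity), N bounded
positive, ΔH and the offset free; initialization is N = 1, ΔH from the
first-injection heat, K_d from the cell concentration at half-saturation.
The fit is deterministic given data and initialization; standard errors
come from the Jacobian at the solution, and a Wiseman c outside [1, 1000]
triggers an advisory warning.

The standard synthetic protocol is 200 µL cell, 13 × 3 µL injections,
25 °C, with syringe:cell concentration ratio 10 (200/20 µM for the
high-affinity fixture, 500/50 µM otherwise), reaching molar ratio ≈ 2.2.
Named fixtures place the generating K_d at 0.3, 3, 16 and 50 µM (the four
affinity regimes of interest), with the dimer fixture at one fifth of the
monomer's K_d (the dimerization fold-enhancement) and the half-sites
fixture booking the cell concentration per protomer with one competent site
per dimer, so its generating N is 0.5.  Enthalpies are representative
exothermic values (−6 to −11 kcal/mol); they scale the heats but not the
recovered K_d or N.

**Precision limits.**  Noise-free fits recover the generating constants to
numerical precision in every regime, including c = 1 (the weak fixture) —
the model is self-consistent and identifiable.  With additive heat noise
the 13-injection curve holds only one or two points in the transition, and
the free dilution offset covaries with K_d, so K_d precision degrades
quickly: at a 0.1 µcal noise floor the median relative K_d error stays
under 15% for c ≥ 5, but at 0.5 µcal it is several times larger regardless
of injection count (verified by simulation at 13/19/25 injections; the
optimizer sits at the global optimum).  N, by contrast, is pinned by the
equivalence point and recovers without bias (< 2% mean error) at c ≥ 10
even at 0.5 µcal.

The advisory affinity regime attached to reports is: strong below 1 µM,
weak above 20 µM (the range where complex predictions should be treated
with suspicion), moderate between, with the 20 µM boundary closed on the
moderate side.

## The synthetic generator

The toy complex is a three-helix-bundle receptor (chain A, 3 × 30 residues,
ideal α-helical geometry: 1.5 Å rise, 100°/residue twist) with a helical
peptide ligand (chain B) docked against helix 1 at a 14 Å axis separation.
Residues are represented by backbone N/CA/C/O, a Cβ, and one
functional-group pseudo-atom along the Cα→Cβ direction at a canonical reach
per residue type — enough for Cα metrics, SASA and the distance classifiers
while staying rotamer-free and fully deterministic.  Interface-facing
positions are leucine; one facing pair is Glu(receptor)/Arg(ligand) with the
side chains pointed at each other and offset 2.5 Å along the helix axis,
giving a genuine salt-bridge geometry without clashes.  The default
interface buries ≈ 160 Å² per side over 7 residue pairs.

Ensemble noise: i.i.d. Gaussian receptor jitter plus a rigid ligand
perturbation (random-axis rotation, Gaussian translation); outlier models
instead displace the ligand 20 Å in a random direction.  Three presets
exercise the verdict regimes: no outliers (5/5 converge), two outliers
(3/5), three outliers (2/5 → failed).  Fabricated confidence tracks give
receptor residues and intra-chain PAE blocks high confidence always; ligand
residues inside the planted binding region get high pLDDT and a low
cross-chain PAE block only in models whose pose is within the consensus
threshold of the truth.  Every generator is a pure function of its spec and
seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real predictions: physically realistic decoys (outliers are
rigid displacements, not plausible alternative binding modes), correlated
confidence errors (real pLDDT/PAE can be confidently wrong), side-chain
rotamers and packing detail, multi-domain receptors with internal motion,
and any coupling between pose error and confidence other than the planted
rule.  The structural acceptance checks are therefore property-based
(exactness, monotonicity, oracle agreement, verdict patterns) rather than
claims of absolute accuracy on real data.

## Numerical choices and degenerate inputs

- Kabsch uses SVD with the determinant correction; reflections never occur.
  Fewer than 3 paired Cα, mismatched lengths, or all-collinear inputs are
  errors.
- Residue pairing is strictly by (chain_id, seq_id); no sequence alignment.
  Unmatched residues are excluded from fits and counted in the report.
- Altloc resolution keeps the highest-occupancy conformer, ties to the
  first in file.  Waters and hydrogens are dropped on read.
- Ranking ties (equal mean pLDDT) break by model id, making ensemble
  assembly order-independent.
- Consensus tie-breaks (equal-size clusters, cluster representative) go to
  the lowest pLDDT rank.
- An empty region call is a valid result, not an error; a flat thermogram
  or one with fewer than 6 injections is an error.
- Reports contain no wall-clock fields; identical inputs give byte-identical
  JSON.

## Problem sizes

The test suite runs entirely on generated fixtures: 114-residue toy
complexes (~580 atoms), 5-model ensembles (up to 60 models in one
statistical check), SASA at 960 points per atom (10 000 in refinement
oracles), 13–25-injection titrations, and 30–50-replicate noise sweeps for
the statistical properties.  The full suite completes in under two minutes
on one CPU; each ITC fit takes well under a second.

## Known limitations

- Contact areas are burial-apportionment estimates; only ranks are
  comparable across CAD implementations.
- The binding-region caller assumes the predictor's confidence is
  informative; confidently wrong predictions produce confidently wrong
  calls.
- The one-site ITC model does not cover multi-site, sequential or
  competitive binding, nor baseline integration from raw power traces.
- Stoichiometry preference uses buried area as the tie-breaker between
  converged ratios; it does not re-rank by composite predictor confidence.
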