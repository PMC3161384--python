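# Methods

This note documents the models, conventions and numerical choices behind
`avbd`, in the spirit of the methods documentation of statsmodels or
msprime: what is computed, under which assumptions, and where the package
made a genuinely open design choice.

## Motif discovery and gene models

β-defensin mature peptides are defined operationally by six cysteines with
the spacing C-X(4–6)-C-X(3–5)-C-X(9–10)-C-X(5–6)-CC. `scan_protein`
enumerates every placement of this pattern (gap bounds are configurable via
`MotifPattern`); overlapping placements are all reported, deliberately —
curation decisions belong to explicit downstream filters, not to the
scanner. `X` never matches a cysteine, and translated stops (`*`) never
match anything, so scanning is conservative on ambiguous sequence.
`scan_nucleotide` translates all six reading frames (N codons become `X`)
and maps matches back to forward-strand nucleotide coordinates.
Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive.

Signal peptides are located by exploiting their strong conservation across
avian defensins: the 2500 bp window upstream of a mature-peptide
annotation (in transcription orientation) is translated in three frames
and slid against a set of reference signal peptides; the best ungapped
identity wins and is attached when it reaches a threshold (default 0.70,
configurable — conservation is described qualitatively in the literature,
so the cutoff is an explicit parameter rather than a constant). No
flank-length cap is applied to motif matches, and no exon structure beyond
signal + mature spans is modelled.

## Peptide physicochemistry

Net charge is the Henderson–Hasselbalch sum: basic groups (H, K, R,
N-terminus) contribute 1/(1+10^(pH−pKa)), acidic groups (D, E, C, Y,
C-terminus) contribute −1/(1+10^(pKa−pH)). The default pKa set is the
Lehninger-style table (D 3.65, E 4.25, C 8.30, Y 10.07, H 6.00, K 10.53,
R 12.48; termini 9.0/3.1) and is printed in CLI output, because published
charge/pI values are only comparable under a stated table — different
calculators use different constants, so third-party tables should be
treated as approximate references. Cysteines are treated as free thiols
(no disulphide modelling). The isoelectric point is the root of the charge
function on (0, 14), found by Brent bisection to |charge| < 1e-4; charge is
strictly decreasing in pH, so the root is unique when it exists.
Hydrophilicity is the plain Hopp–Woods (1981) average.

## Expression: TPM and τ

The expression model matches a 454-style cDNA count design: reads are
assigned to loci per tissue, and TPM is `count / library_size × 10⁶` with
**no transcript-length normalisation** — a definition verified by
back-computing integer counts from published tables. τ follows the
log-transformed tissue-specificity index:

τ = Σᵢ (1 − log xᵢ / log x_max) / (N − 1)

over N tissues, with xᵢ the **unrounded** TPM and xᵢ := 2 substituted for
tissues with zero reads (the pseudo-count is applied on the TPM scale, and
only to zero-count tissues). Using unrounded TPMs matters at the third
decimal of τ. Estimates based on ≤ 3 reads in total are flagged
`discarded` rather than deleted, and zero-expression loci are retained in
tables so absence of expression is reported. The log ratio makes τ
independent of the logarithm base. The index presumes x ≥ 1; with
libraries so deep that a single read maps below 1 TPM the raw sum can
leave [0, 1], so τ is clipped — with the pseudo-count floor of 2 this does
not arise in realistic count tables.

## Pairwise rates: NG86 and GY94 ML

`ng86_pairwise` implements Nei–Gojobori (1986) counting as the transparent
baseline: per-codon synonymous site fractions are computed over the
non-stop single-nucleotide neighbourhood (stop neighbours excluded from
numerator and denominator), site counts are averaged over the two
sequences, multi-hit codons are resolved by averaging synonymous /
nonsynonymous steps over all minimal substitution pathways that avoid
stops, and proportions are corrected with Jukes–Cantor,
d = −¾ ln(1 − 4p/3). Proportions at or past the singularity (p ≥ ¾) leave
the distance undefined and the pair flagged `saturated`; summaries
(means/SEs of dN, dS, ω) are taken over defined pairs only, matching the
standard practice of excluding saturated paralog comparisons. A κ-corrected
(yn00-style) counting mode is deliberately out of scope: inferential
comparisons should use the ML route, and the plain NG86 counts are
oracle-checkable by hand.

`PairwiseCodonML` fits the Goldman–Yang (GY94) codon model to one sequence
pair: q_ij = π_j κ^[transition] ω^[nonsynonymous] over the 61 sense codons
(standard code; stop codons excluded from the state space), with F3×4
frequencies estimated from the data (a quarter-count per nucleotide per
position guards zeros) and free parameters (t, κ, ω). By reversibility only
the total divergence t is identifiable. dN and dS are derived from the
fitted rate-matrix flows, with sites counted by the mutational opportunity
of the same model at ω = 1, so dN/dS equals the fitted ω exactly.

## Site-class mixtures and tests for positive selection

`CodonSiteModel` fits the standard nested site models on a fixed tree:
M1a (ω₀ < 1, ω₁ = 1), M2a (adds ω₂ ≥ 1), M7 (ω ~ Beta(p, q)), M8 (beta
plus a free ω_s ≥ 1 class with weight 1 − p₀) and M8a (M8 with ω_s = 1).
Choices that matter:

- **Likelihood.** Felsenstein pruning over the 61 sense codons, vectorised
  over compressed site patterns with per-node rescaling. Transition
  matrices come from the symmetric eigendecomposition that reversibility
  allows. Branch lengths are expected substitutions per codon under the
  mixture: all class matrices share one scale so the mixture-averaged rate
  is 1 (the convention of mainstream codon-model software). The pruning
  path is verified in the test suite against brute-force enumeration over
  all internal-node states on small trees.
- **Beta discretisation.** 10 equal-probability classes by default, each
  represented by its conditional mean (computed from the incomplete beta
  function; medians available via `beta_representative="median"`).
- **Optimisation.** Bounded L-BFGS-B on natural-scale parameters
  (κ ∈ [0.05, 50], beta shapes ∈ [0.005, 99], ω_s ∈ [1, 50], proportions in
  the open unit interval), one deterministic start from model-specific
  defaults plus seeded random restarts (default 5 starts in total; the
  heavier simulation tests use 1–2, which recover the generating
  parameters reliably at their problem sizes). Convergence at
  ftol = 1e-8; the best optimum across starts is kept and the seed
  recorded in the result.
- **LRTs.** 2Δℓ against χ² with df = difference in free parameters: M1a vs
  M2a at df 2, M7 vs M8 at df 2, M8a vs M8 at df 1. Statistics within
  −1e-6 of zero are clamped; anything more negative raises. The boundary
  mixture refinement for M8a-vs-M8 is noted in result metadata but not
  applied, keeping the conventional (slightly conservative in the
  direction of the alternative) df = 1 test.
- **Site identification.** Posteriors are naive empirical Bayes (MLEs
  plugged in); sites are reported when their posterior mass on ω > 1
  classes exceeds a threshold (0.95 / 0.99 tiers). A full Bayes empirical
  Bayes integration over parameter uncertainty is a known extension point;
  with the NEB approximation, site lists near the threshold should be read
  with that in mind. M8a yields an empty site list by construction; M1a
  and M7 have no ω > 1 class and querying them is an error.
- **Branch lengths** are taken from the input tree by default;
  re-estimation can be layered on by the caller (the simulators always
  emit trees with known lengths, which is also the typical re-analysis
  setting where a dS- or ML-derived tree exists).

`compare_omega_classes` compares two sets of ω estimates (e.g. duplicated
vs non-duplicated genes) with a Mann–Whitney U test (midranks, normal
approximation with tie correction, two-sided) plus a seeded Monte-Carlo
permutation test on |difference of group means| with the standard +1
correction, so the permutation p can never be 0 and is reproducible given
the seed. An exact U p-value is attached for small tie-free samples.

## Distance trees

`neighbor_joining` is the Saitou–Nei agglomeration with the standard Q
criterion; ties break on (row, column) order. Negative intermediate branch
lengths are clamped to zero with the deficit moved to the sister branch,
preserving the joined pair's path length; NJ therefore reconstructs any
additive matrix exactly (a property the tests exercise against randomly
generated trees and against scikit-bio's implementation). NJ requires a
complete matrix — undefined (saturated) entries must be imputed or the
taxa excluded by the caller.

`ls_branch_lengths` re-fits branch lengths on a fixed topology by
minimising Σ (d_ij − p_ij)² / d_ij^P over non-negative lengths — the
Fitch–Margoliash criterion with the conventional P = 2 default, ordinary
least squares at P = 0 — solved exactly as a non-negative least-squares
problem on the edge-incidence design matrix. Undefined distances are
omitted from the sum (each taxon must retain at least one defined pair);
zero distances get unit weight to avoid an infinite-weight singularity. A
rooted input topology is derooted first, since the two root edges are not
separately identifiable from leaf-to-leaf distances. The intended use is
the classical display workflow: NJ (or any) topology, branch lengths
re-estimated from a synonymous-distance matrix so depths track divergence
time rather than selective rate variation.

`midpoint_root` places the root halfway along the longest leaf-to-leaf
path, with ties broken on the lexicographically smallest leaf-label pair;
zero-diameter trees root at the first leaf's attachment with no meaningful
depth. `linearize` is a clock projection: each node's height above the
leaves becomes the mean of its current node-to-leaf path lengths over
descendant leaves, lifted minimally where needed to keep parents above
children; branch lengths become height differences, so all leaves end up
coeval and an already-ultrametric tree is a fixed point. This is a display
transform, not a rate-test-based linearisation: no hypothesis about
clock-likeness is tested.

`bootstrap_support` resamples alignment columns (codon columns, preserving
within-codon structure), rebuilds the NJ tree per replicate from a
pluggable distance function (default: proportion of differing codons), and
annotates the full-data tree's internal splits with replicate percentages.

## Synthetic data

The generators produce data with exactly the structure the analysis
assumes, which defines what passing tests do and do not show.

- **Clusters.** Genes are planted on a background chromosome with
  configurable GC content; each gene is a random motif-satisfying mature
  peptide (inter-cysteine gaps drawn within the pattern bounds,
  cysteine-free elsewhere) plus a conserved signal peptide at a truncated-
  normal upstream offset (mean 700 bp, sd 200, capped at 2500 — the
  empirical geometry of avian defensin gene models), on a random strand.
  Duplication events plant verbatim copies. The assembled chromosome is
  re-scanned and rejected until the scan recovers exactly the planted
  genes, so noise-free recall/precision 1.0 is a construction invariant,
  and the truth object records every span. The default signal peptide is a
  synthetic cysteine-free stand-in, not a database sequence. Not emulated:
  sequencing error, assembly artefacts, introns/UTRs, or homology decay
  between duplicates — scanner performance on real, degraded gene copies
  is outside what these tests demonstrate.
- **Alignments.** Each codon site draws an ω class once (shared across the
  tree); the root codon comes from the equilibrium frequencies and
  children are sampled from exact eigendecomposition transition matrices,
  with the same mixture-rate branch-length convention as the fitter.
  Alignment gaps, recombination, and among-site rate variation beyond the
  ω mixture are not simulated.
- **Counts.** Read counts are independent Poissons with mean
  TPM × library_size / 10⁶ per locus × tissue — the independence the τ
  computation implicitly assumes; library sizes are parameters, not
  resampled, and overdispersion (biological replication) is not modelled.

Simulation-based tests use deliberately modest problem sizes chosen for
statistical adequacy: site-model recovery uses 9 taxa × 100 codons over 20
seeded replicates under the published M8-style generating values
(p₀ = 0.64, beta(0.005, 0.008), ω_s = 3.65); class-separation experiments
use 12 "duplicated" vs 10 "orthologous" pairs at ω = 1.0 vs 0.3 with
300-codon pairs; pairwise recovery uses 500-codon pairs. At these sizes
the ML ω estimator's replicate spread is wide (roughly ±0.5 around ω = 1.8
at 500 codons) — the tests assert recovery at that honest resolution.

## Known limitations

- NEB rather than BEB site posteriors (see above).
- No branch or branch-site models; no Bayesian tree inference; the NJ
  topology is the only topology search.
- `PairwiseCodonML` and the site models assume in-frame, stop-free,
  whole-codon-gapped alignments and will refuse anything else.
- The LRT p-values use the conventional χ² reference; near-boundary nulls
  make them conservative for detecting selection, which is the usual
  trade-off accepted in this test family.
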