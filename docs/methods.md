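# Methods

## The demographic models

Two diploid demes A (the "maximus-like" lineage) and B (the
"jacobaeus-like" lineage) of effective sizes `N_pma`, `N_pja` descend
from an ancestral deme of size `N_anc` that split `T_S` generations
ago.  Five models differ only in when migration is active (backward in
time): never (SI), throughout `[0, T_S)` (IM), only early
`[T_1, T_S)` (AM), only recently `[0, T_1)` (SC), or in a recent
window that already closed, `[T_2, T_1)` (SCS).  Migration parameters
`m_mj` and `m_jm` are per-generation migrant proportions; forward
A→B migration at rate `m_mj` means a lineage currently in B traces its
ancestry into A with probability `m_mj` per generation, which is how
the simulator applies it.  Free-parameter counts: SI 4, IM 6, AM/SC 7,
SCS 8.

The structured coalescent is simulated as a continuous-time
competing-risks process: each lineage pair in a deme of size `N`
coalesces at rate `1/(2N)` per generation, each lineage migrates at
its backward rate while the model's window is open, and at `T_S` all
lineages pool into the ancestral deme.  Two implementations exist —
a readable pure-Python engine (`coalescent.py`) and a numba-compiled
kernel (`_kernels.py`) used in the inference hot path; they implement
the same process with different random streams and are cross-checked
statistically in the test suite.

## Expected SFS and composite likelihood

The expected folded joint SFS under a parameter set is obtained by
branch-length accumulation: every branch of a simulated genealogy
contributes its length to the unfolded cell indexed by its descendant
counts per deme.  This is the (mutation-rate-free) expectation of the
SFS shape, with far lower Monte-Carlo variance than dropping
mutations.  Spectra are folded onto minor-allele counts (boundary
cells split half/half with their mirror, the dadi/easySFS convention),
the monomorphic corners are masked, empty cells floored, and the rest
normalised to proportions.  The composite log-likelihood is
`Σ O_ij log10 E_ij` over unmasked cells.

**Scale anchoring.**  Masked, normalised proportions are exactly
invariant under `N → cN`, `T → cT`, `m → m/c`: only parameter ratios
are identifiable from the spectrum shape.  When absolute values are
wanted, the fitted objective adds a Poisson term for the total SNP
count with mean `n_loci · μ · E[total branch length]`, where `μ` is
the known per-locus mutation rate — the standard practice of anchoring
the coalescent time scale with a mutation rate.  All reported absolute
parameter estimates use this anchor.

**Optimisation.**  The likelihood surface is rugged: it carries a
narrow diagonal valley trading split depth against ancestral size, and
needle-like conditional optima for the weakly informed coordinates
(the recent gene-flow stop `T_2`, the minor migration rate).  The
search therefore proceeds in stages, all under common random numbers
(CRN) so each stage sees a deterministic surface:

1. structured starts — method-of-moments guesses (sizes from the
   anchored total branch length, split times on a ratio-2 geometric
   ladder spanning 0.5–8 × 2N, fine enough that some start lands
   within √2 of any split depth in range) plus, for each model, the
   best fit of the next-simpler nested model (SI → IM → {AM, SC} →
   SCS), also tried at several time scales;
2. short Nelder–Mead triage of every start on a cheap surface
   (600 genealogies per evaluation by default in the studies); the
   endpoints are re-ranked with single high-precision evaluations,
   because the cheap surface's empty-cell floor systematically favours
   shallow-split basins; then a fuller simplex from the best two
   basins, the winner again chosen on the high-precision stream;
3. refinement on a high-precision shared CRN stream (3000 genealogies;
   the same stream for every model fitted to one spectrum, so AIC
   differences are not dominated by independent Monte-Carlo noise):
   simplex, a bounded Powell pass, per-coordinate line searches, an
   explicit two-point profile of the minor migration rate, and an
   iterated 1-D pin of `T_2` on a 4× larger stream.  Only the two
   AIC-leading models receive the expensive refinement.

Oracle runs started at the generating truth recover every parameter to
within ~5%, confirming that remaining estimation error is optimisation
transport, not lack of information, at the study sizes used.

Models are ranked by `AIC = 2k − 2 ln(10) · logCL10` (the anchored
likelihood when an anchor is used; the anchor term has the same form
for every model, so rankings are unaffected).  No effective-dof
correction for composite likelihoods is applied.  Uncertainty comes
from a parametric bootstrap: multinomial spectra of the observed size
drawn from the fitted proportions are refitted and per-parameter
percentile intervals taken; with cold restarts the intervals propagate
the full estimator variance, including optimiser scatter.

## Synthetic studies

The generator emulates a two-species RAD-seq study: short
(150 bp) non-recombining loci scattered over several chromosomes, one
genealogy per locus, infinite-sites mutations with
`theta_per_locus = 4 N_pma μ_locus` (default 4.0 — a hyperdiverse
marine-bivalve scale, ~0.027/bp), diploid genotypes formed by pairing
lineages, and GQ/DP noise (`DP ~ NegBinom(mean 20, dispersion 5)`,
`GQ = min(99, Poisson(40))`, no-read genotypes missing) chosen so the
quality filters have something to remove.

Planted **divergent regions** model barriers to gene flow: their loci
are simulated without migration and with a locally reduced `N_e`
(default ×0.3, a sweep-like diversity loss).  In `barrier+linked`
mode all loci of a region share a single genealogy, and a fraction
(default 0.25) of their mutations become **inversion orientation
markers**: deme-B lineages carry one of two orientations (minor
frequency 0.25, drawn as an exact count so the markers always
segregate), and marker sites are fixed differences between the
orientations — mutually in complete LD across the whole region within
deme B, absent from deme A.  This reproduces the empirical signature
of a segregating inversion: elevated F_ST and d_xy, reduced π,
and long-range within-species LD confined to the region.  What the
generator does **not** emulate: intra-locus recombination, linked
selection outside the planted regions, allele-frequency-dependent
genotyping error, paralogy/mapping artefacts, and base-composition
structure — so passing tests demonstrate estimator correctness and
qualitative pattern recovery, not robustness to those artefacts.

Default study conditions for the recovery analyses (chosen once):
all `N = 500`, `T_S = 3000`, `T_1 = 300`, `T_2 = 10` generations,
strong asymmetric migration `m_jm = 0.005` (2Nm = 5, the dominant
direction, B→A forward) and `m_mj = 0.0005`, 2000 loci, projection
(20, 10) haploids.  Migration much stronger than this homogenises the
demes almost completely during contact and makes the model family
near-degenerate.

## Estimators

* **Filtering** follows RAD practice: genotypes with GQ or DP at or
  below 5 are masked (strict "greater than five"); sites genotyped in
  < 80% of individuals are dropped, then samples with > 80%
  missingness; the pooled minor-allele-frequency filter keeps sites
  with MAF strictly above the threshold.  The SFS is always built from
  the non-MAF-filtered matrix (a provenance flag enforces this).  Six
  dataset variants reproduce common sensitivity analyses (per-species
  call rate; MAF > 0.01; no MAF; exact-test HWE filtering within each
  sampled population, removing sites that violate in all, or in at
  least half, of the populations).
* **F_ST** per site uses the Weir–Cockerham (1984) two-population
  variance components `(a, b, c)`; a window's value is
  `Σa / Σ(a+b+c)` (negative values preserved).  Windows are
  non-overlapping 1-based tiles; windows with fewer than `min_snps`
  SNPs stay in the output but are unusable for outlier calling.
  Outliers are windows at or above the type-7 empirical 95th
  percentile (ties all flagged).
* **π** per window sums the unbiased per-site heterozygosity
  `2x(n−x)/(n(n−1))` over variant sites and divides by the window
  length.
* **d_xy** uses all-sites records: differing between-deme allele pairs
  over comparable pairs, summed over sites before dividing, so missing
  genotypes down-weight a site instead of biasing it.
* **r²** is the squared Pearson correlation of diploid dosages over
  pairwise-complete individuals (the PLINK-style unphased estimator);
  LD decay is fitted to the Hill–Weir (1988) expectation on
  100-bp-binned means by nonlinear least squares over
  `rho_per_bp ≥ 0`.  The background r² is the mean beyond the top
  distance decile, or a caller-supplied value — region-restricted fits
  use the genome-wide background, mirroring how long-range LD is
  reported against a genome-wide baseline.  The decay distance is the
  smallest distance at which the fitted curve comes within
  ε = 0.005 of the background, capped at the largest observed
  distance.
* **Effect classification** is most-severe-first (loss-of-function >
  missense > synonymous > splice region > UTR > intron >
  up/downstream > intergenic), with codon substitution under the
  standard genetic code, strand-aware; loss of function covers
  stop-gained, start-lost and splice donor/acceptor (first two
  intronic bases).  Up/downstream extends 5 kb; the splice region is
  intronic positions 3–8 bp — common annotation-tool defaults.  Genes
  whose CDS length is not a multiple of 3 are flagged and excluded
  from coding calls.
* **GO enrichment** is a per-term one-sided Fisher exact test with no
  multiple-testing correction; annotations propagate to ancestors when
  a parent map is supplied.  The optional "elim" algorithm processes
  terms most-specific-first and removes the genes of significant
  children from their ancestors; the heavier "weight" style
  decorrelation is intentionally out of scope.

## Numerical and design choices

* Fold boundary mass split 0.5/0.5; monomorphic corners masked.
* Expected-SFS floor: 1e-10 by default; the fitting studies use 1e-6
  because a harsher floor makes the optimiser chase which cells happen
  to be empty at finite Monte-Carlo size.
* Search bounds: sizes `[10, 1e6]` diploids, split time `[1, 1e7]`
  generations, migration `[1e-10, 0.5]`; internal coordinates are
  log-scaled (sizes, times), with inner epoch boundaries as logistic
  fractions of the enclosing epoch so the ordering
  `T_2 ≤ T_1 ≤ T_S` holds by construction.
* Diagnostic-SNP calling tolerates missing genotypes (fixedness judged
  among genotyped calls) behind a per-species call-rate guard of 0.8;
  a strict complete-data mode is available.
* Gene assignment: containing gene, else nearest by span distance,
  ties to the lower start coordinate.
* Bootstrap CIs use order-statistic percentiles (`n_boot = 2` gives
  exactly the min/max).
* Study sizes in the test suite (20 replicates for the recovery
  studies; 600-genealogy evaluations; 3000-genealogy scoring; small
  landscapes of 4 × 400 kb chromosomes with 160 loci) are the
  package's scaled-down defaults for routine validation; all are
  configurable upward.

## Known limitations

* Composite-likelihood AIC ignores site linkage within loci; model
  ranks are robust in the recovery studies but the AIC scale is not a
  calibrated evidence measure.
* Absolute parameter estimates require the mutation-rate anchor; shape-only
  fits identify ratios.
* The recent gene-flow stop `T_2` is the hardest parameter: its
  estimate can wander by ~2× at desk-scale data even when the
  likelihood at the truth is sharply peaked, because its optimum is
  conditionally coupled to the other parameters.
* The LD decay distance depends on the ε convention and on the
  sampling floor `1/n`; with small samples the fitted curve approaches
  the background slowly and decay distances are longer than the
  visual "elbow".
* The generator's loci are unlinked outside divergent regions, so
  genome-wide LD decays to the sampling floor at the locus scale
  rather than over an explicit recombination map.
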