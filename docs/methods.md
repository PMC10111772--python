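# Methods

This note records the models behind each stage, the defaults and why they
were chosen, and the numerical and design decisions a maintainer would want
spelled out. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and site filtering

Genotypes live in a dense samples × sites matrix of ALT-allele dosages
(0/1/2, −1 missing) with a pandas site table carrying the VCF annotations
(QUAL, QD, FS, MQ, DP, MQRankSum, ReadPosRankSum) and an ancestral-allele
state per site (`ref`/`alt`/`unknown`). Internally all intervals are 0-based
half-open; VCF and BED conventions apply only at I/O. Multiallelic records,
indels and MNPs are dropped at read time; half-calls become missing and
phasing is discarded.

The hard filters follow common GATK practice for mammal re-sequencing
panels. Two wordings in that practice are ambiguous and were fixed as
follows:

- *"unobserved variant allele < 10%"* is read as a per-site missing-call
  limit: sites with ≥ 10% missing genotype calls are removed. The alternative
  reading (a minor-allele constraint) would discard real rare variation,
  which the downstream load analyses need.
- The overall-depth bounds (⅓×, 3×) apply to the per-site **summed** DP
  across samples, against the mean summed DP of the input panel. Because the
  mean is recomputed from whatever matrix is passed in, re-filtering an
  already-filtered panel is idempotent only when the surviving sites do not
  shift the mean across a bound; `FilterConfig.mean_depth` pins the mean
  explicitly when exact reproducibility across subsets matters.

Filters whose annotation is absent are skipped per rule (logged), never
fatal, so simulator output and external VCFs with sparse INFO fields run
through the same code path. Assembly-gap intervals come from a BED file or
from N-runs in a reference FASTA; with neither, the 5-bp gap rule is skipped
with a warning.

Polarization assigns each site the outgroup sample's homozygous allele as
ancestral; heterozygous or missing outgroup calls mark the site unknown, and
unknown sites are excluded from every derived-allele analysis (counted in
reports).

## The synthetic-data generators

### Forward Wright–Fisher simulator

Discrete non-overlapping generations of diploids with tracked sexes.
Reproduction is viability-based: a father and mother are drawn uniformly
from the males and females of the parent pool, gametes recombine with
Poisson crossovers (uniform rate per bp), and the zygote **survives to
adulthood with probability equal to its fitness** — multiplicative over
sites, 1 − hs per heterozygous and 1 − s per homozygous derived genotype.
Viability (rather than fertility-weighting) was chosen deliberately: the
sampled final generation is then itself post-selection, so recessive lethal
homozygotes never appear among genotyped adults, matching how real sampled
animals are survivors. A scenario can restrict selection to named
populations (`selected_in`), which is how the purging analyses pair a
selected line with an otherwise identical neutral control.

Demography is a list of populations with per-generation size maps, splits
(new populations copy wild-caught individuals from a source, optionally
exactly n males + m females — the founder event), one-generation admixture
pulses (a fraction of the target's offspring draw both parents from the
source), and an optional studbook-like mating mode that avoids full-sib
pairs. Pedigree (id, sire, dam, sex, generation, population), per-individual
ancestry fractions (basis vectors reset at each population's foundation) and
per-site truth (ancestral allele, mutation class, s, h, initial frequency)
are recorded.

**Initialization.** Standing variation is drawn directly from the neutral
site-frequency spectrum (site count ~ Poisson(θ·L·a_n), frequencies ∝ 1/i) in
linkage equilibrium, instead of a long mutation–drift burn-in; small
scenarios therefore start at equilibrium diversity immediately (the test
suite verifies mean π against both the coalescent expectation θ = 4Nμ and an
independent coalescent simulator). Sites in selected classes initialize at
the lowest frequency class (singletons) — an approximation to
mutation–selection balance; drawing deleterious variants from the neutral
spectrum instead gives biologically impossible lethal loads that extinguish
founder lines. New mutation is Poisson per generation under infinite sites.

**Scale.** Defaults are scaled down so scenarios run in seconds: 2–3
chromosomes of 6–10 Mb, diploid sizes ≤ 60, per-site θ of 1–4 × 10⁻⁴ and a
mutation rate of 1 × 10⁻⁸/bp/generation. The real-genome parameters the
package carries as metadata (μ = 3.5 × 10⁻⁹, generation time 5 years) are
not used to drive toy runs. Products 4Nμ and the founder/bottleneck depths
are the quantities the scenarios preserve.

**Mutation classes.** Defaults: HIGH (stop-gain-like) s = 0.9, h = 0.05;
MODERATE (missense-like) s = 0.03–0.05, h = 0.2; LOW (synonymous) s = 0.
The HIGH class is *nearly* recessive rather than h = 0 exactly: severe
loss-of-function variants empirically express a few percent in
heterozygotes, and that small heterozygous cost is what lets a toy-sized
population purge them measurably — with h = 0 exactly, soft viability
selection in a small population mostly prevents fixation while drift noise
dominates the frequency deficit. Class fractions in the purging scenario
(HIGH 8%, MODERATE 6%, LOW 10% of sites) are inflated far above real exome
density so that load tables carry countable sites at desk scale.

**What the simulator does not emulate:** linked-selection
(background-selection) correlations beyond direct linkage, gene conversion,
variable recombination/mutation maps, overlapping generations, sex
chromosomes (autosomes only), genotyping error and depth-dependent missing
data (synthetic INFO/DP fields are drawn from passing distributions unless a
scenario plants failures). Passing tests therefore demonstrate estimator
correctness and qualitative signatures, not calibration to any real genome.

### Unlinked-site drift sampler

For frequency-based statistics at 5 × 10⁴–10⁵ sites, per-site independent
evolution along a population tree: ancestral derived frequencies from the
1/p neutral density (truncated at 0.01), Balding–Nichols beta drift per
branch (variance F·p(1−p)), admixture as linear frequency mixing, binomial
diploid genotypes at the leaves. Terminal drifts around 0.12 reproduce
subspecies-level F_ST (~0.2–0.3). Linkage is absent by construction, so this
generator is used only where sites enter additively (D, f4, F_ST, null
calibrations), never for ROH or IBD-segment questions.

### Pedigree inbreeding

Wright's F_p is the kinship of the parents, computed by the standard
recursion (founders unrelated and non-inbred) with memoization and cycle
detection; the test suite checks it against an independently coded tabular
(additive-relationship-matrix) oracle.

## Statistic-level choices

- **Windows** tile each chromosome from coordinate 0 in fixed steps
  (defaults 20 kb / 10 kb); the trailing window keeps its true span. Window
  statistics divide by the full window span in bp, the convention of common
  windowed-diversity tools; a callable-sites denominator is available via the
  per-window site counts. Per-site π uses the unbiased 2j(n−j)/(n(n−1)) with
  each site's own called-copy count; Watterson sums 1/a_n per segregating
  site with that site's own n.
- **F_ST** defaults to Weir–Cockerham 1984 variance components with the
  ratio-of-sums ("weighted") genome-wide estimator; per-window values are
  reported as computed, negatives included. Hudson's estimator is an option
  for sensitivity. The population matrix mirrors the usual layout: weighted
  F_ST above the diagonal, per-window SDs below.
- **IBD moments** follow the PLINK `--genome` construction: expected
  IBS-state probabilities given IBD state from sample allele frequencies with
  the (a−1)(a−2)(a−3)-style small-sample corrections, solved sequentially for
  Z0, Z1, Z2, bounded to [0,1] and renormalized. Frequencies come from the
  full sample set; pairs with < 50 informative co-called sites are flagged
  low-confidence, and PI_HAT ≥ 0.05 is flagged to mirror the customary
  reporting threshold.
- **PCA** mean-imputes missing dosages, centers by 2p̂ and scales by
  √(2p̂(1−p̂)) (EIGENSTRAT scaling), then takes an SVD; the sign convention
  (largest-magnitude coordinate positive) makes output deterministic.
- **Neighbor joining** is implemented directly so the negative-branch
  policy is exactly: clamp to zero and move the deficit onto the sibling
  edge. Trees are scikit-bio `TreeNode` objects (Newick I/O, outgroup
  rooting); scikit-bio's own NJ serves as an independent topology cross-check
  in tests. Bootstrap support resamples sites (block resampling available),
  rebuilds the distance matrix and tree per replicate, and scores reference
  bipartitions normalized to exclude a fixed reference taxon.
- **ROH** reproduces the PLINK `--homozyg` algorithm with the window
  hit-rate threshold at the emulated tool's default (0.05, recorded in
  output); there is no segment-level heterozygote cap beyond the window
  allowance. SNPs near chromosome ends are rated over the windows that
  actually contain them; chromosomes with fewer SNPs than one window yield no
  calls. The F_ROH denominator defaults to the summed contig lengths from the
  VCF header and is configurable for cross-panel comparability.
- **D and f4** work on derived-allele frequencies (multi-sample
  populations; singleton individuals reduce to genotype counts).
  Delete-one block-jackknife SEs use consecutive blocks of 1,000 used sites
  by default, with a floor of 20 blocks — with fewer blocks the jackknife
  variance is unusable, which short inputs would otherwise hit silently.
  For f4-ratios the A and B stand-ins for the donor clade must be disjoint
  sample sets: using the same samples for both puts their sampling noise
  into the denominator only and biases α toward zero, so the default
  per-individual quartets split each donor population into halves. The
  admixture significance test is the jackknife Z of the numerator f4;
  Benjamini–Hochberg FDR is applied across all per-individual tests, and
  summaries report both FDR-retained and unfiltered means (the choice of
  averaging is ambiguous in common practice, so both are emitted).
- **Effect classification** translates ref/alt codons under the standard
  code with strand-aware complementing, phase-aware codon indexing, splice
  disruption fixed at ±2 bp of CDS-boundary introns, most-severe-effect-wins
  across overlapping transcripts, and exclusion (with a warning) of sites
  whose REF disagrees with the reference sequence. Non-coding sites are
  excluded from load tables entirely.
- **Load accounting** counts homozygous (derived dosage 2) and heterozygous
  (dosage 1) genotypes per sample and class; between-population comparisons
  use Welch's unequal-variance t-test on per-sample homozygote counts.
- **SFS** is unfolded on the derived allele at a fixed copy number (the
  modal called-copy count by default); sites with more called copies project
  down hypergeometrically (or are excluded, per flag), sites with fewer are
  excluded; fixed classes 0 and n are never part of the polymorphic
  spectrum. The display binning shows counts below 10 individually and mean
  sites per count class in intervals above.
- **Rxy** uses the frequency form L_X∉Y = Σ d_X(1−d_Y) with a
  delete-one-chromosome jackknife CI (block option available). It is
  reported raw by default; normalization by the LOW-category ratio is a flag,
  since published usage varies and the raw ratio is the more transparent
  quantity. The exact identity Rxy(X,Y)·Rxy(Y,X) = 1 is asserted in tests.
- **K-mers** are counted exactly as 2-bit-packed canonical codes (k ≤ 31);
  the depth-1 class is excluded from peak finding by default (error k-mers on
  real data). Note the estimator's peak measures *k-mer* coverage,
  C·(L−k+1)/L, slightly below read coverage.

## Pipeline and determinism

`run_pipeline` validates the configuration (paths, stage names, the
polarization dependency of the derived-allele stages) before any stage runs.
The top-level seed fans out per stage as
`(seed·1000003 + crc32(stage)) mod 2³¹`, so single stages re-run in
isolation reproduce their output; identical config + seed gives
byte-identical TSVs. The manifest records inputs, parameters, per-stage row
counts and seeds.

## Known limitations

- The ROH scanner is a faithful re-derivation of PLINK's documented
  windowing but has no HMM/likelihood mode, and population-level ROH-island
  analyses are out of scope.
- f4-ratio estimates assume the configured quartet topology; with a
  misspecified donor clade α is not interpretable, and the package does not
  attempt topology discovery.
- The effect classifier handles single-nucleotide substitutions in CDS plus
  ±2 bp splice sites only — no UTR/regulatory classes, no multi-transcript
  isoform resolution beyond severity, no indel consequences.
- Acceptance-scale simulations are scaled down (tens of diploids, tens of
  megabases); the problem sizes used are stated in `scripts/acceptance.py`
  and the test docstrings.
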