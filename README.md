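# founderpop

Population-genomic analysis of captive populations descended from a handful
of wild-caught founders — the situation of conservation-breeding programs
such as the South China tiger's, where every living animal traces back to
two male and four female founders split across two zoo lineages.

The package takes multi-sample SNP data (VCF) plus a sample→population map
and runs, as one pipeline or as individual library calls:

- **Site filtering** — GATK-style hard filters (QD < 2, FS > 60, MQ < 40,
  QUAL < 30, DP < 4, MQRankSum < −12.5, ReadPosRankSum < −8), summed-depth
  bounds at (⅓×, 3×) of the panel mean, a <10% missing-call rule, and removal
  of SNPs within 5 bp of assembly gaps.
- **Diversity** — per-individual heterozygosity; sliding-window nucleotide
  diversity π and Watterson's θ<sub>W</sub> = S / (a<sub>n</sub> · L) in
  20-kb windows stepping 10 kb; pairwise F<sub>ST</sub> (Weir–Cockerham 1984
  variance components, ratio-of-sums "weighted" estimator; Hudson as an
  option).
- **Relatedness and phylogeny** — IBS / p-distance matrices, PLINK-style
  method-of-moments IBD sharing (Z0, Z1, Z2, PI_HAT = Z1/2 + Z2), genotype
  PCA, Saitou–Nei neighbor joining with site-bootstrap branch support and
  outgroup rooting.
- **Runs of homozygosity and inbreeding** — the PLINK `--homozyg` sliding
  100-SNP-window scanner (≤2 hets, ≤5 missing per window, 5% hit-rate
  threshold, ≥100 SNPs, ≥100 kb, ≥1 SNP/10 kb, 100-kb gap split);
  F<sub>ROH</sub> at the 100 kb / 1 Mb / 2 Mb thresholds; the
  excess-homozygosity coefficient
  F<sub>H</sub> = (O<sub>hom</sub> − E<sub>hom</sub>) / (N − E<sub>hom</sub>);
  Wright's pedigree F<sub>p</sub> by path counting.
- **Introgression** — Patterson's D = Σ(ABBA − BABA)/Σ(ABBA + BABA) from
  derived-allele frequencies with delete-one block-jackknife Z scores
  (|Z| > 3 flagged); f4-ratio admixture proportions
  α = f4(A,O;X,C) / f4(A,O;B,C); per-individual mean introgression ratios
  with Benjamini–Hochberg FDR.
- **Mutation load** — a minimal coding-effect classifier over GFF3 + FASTA
  (stop-gain/-loss, start-loss, splice ±2 bp → HIGH; missense → MODERATE;
  synonymous → LOW), per-individual homozygous/heterozygous derived counts
  per impact class, the unfolded site-frequency spectrum, and the relative
  load statistic R<sub>XY</sub> = Σd<sup>X</sup>(1−d<sup>Y</sup>) /
  Σd<sup>Y</sup>(1−d<sup>X</sup>) with a delete-one-chromosome jackknife —
  R<sub>XY</sub> < 1 meaning a relative deficit of that class in X
  (genetic purging).
- **K-mer genome sizing** — canonical 17-mer histograms and
  genome size = k-mer count / peak depth.

A forward Wright–Fisher simulator (`founderpop.synthetic_data`) generates
panels with known truth — pedigrees, true ancestry fractions, per-site
selection coefficients — for six diverged populations, a 2♂ + 4♀ founder
event into two captive lineages, admixture pulses, and three deleterious
mutation classes under viability selection. A fast per-site drift sampler
(Balding–Nichols branches, binomial genotypes) covers the frequency-based
statistics at 50,000+ sites.

## Worked example

Simulate a captive-breeding scenario (wild source, two lineages founded by
1♂ + 2♀ each, a 15% admixture pulse from a diverged donor into lineage 1)
and run the core statistics:

```python
from founderpop import synthetic_data as sd, diversity as dv, roh as rh, introgression as ig
from founderpop.variant_store import polarize_by_outgroup

res = sd.simulate(sd.founder_captive_config(seed=3, n_generations=14,
                                            pulse_fraction=0.15))
gm, spec = res.genotypes, res.population_spec

for p in ("wild", "lineage1", "lineage2"):
    print(p, dv.diversity_windows(gm, p, spec)["pi"].mean())
print(dv.pairwise_fst(gm, "lineage1", "lineage2", spec).fst)

seg = rh.detect_roh_all(gm, samples=spec.samples_in("lineage2"))
tab = rh.inbreeding_table(gm, seg, samples=spec.samples_in("lineage2"))
print(tab[["F_ROH_100kb", "F_H"]].mean())

pol = polarize_by_outgroup(gm, "outgroup_1")
d = ig.d_statistic(pol, spec, "lineage2", "lineage1", "donor", "outgroup")
print(d.d, d.z)
```

prints (abridged):

```
pi[wild]     = 1.59e-04 per bp
pi[lineage1] = 1.40e-04 per bp
pi[lineage2] = 1.22e-04 per bp
FST(lineage1, lineage2) = 0.282
lineage2 mean F_ROH(>=100 kb) = 0.162, mean F_H = 0.100
lineage2 pedigree F_p range = 0.341-0.427
D(lineage2, lineage1; donor, outgroup) = 0.089, Z = 5.5
true mean donor ancestry in lineage1 = 0.199
```

Diversity declines from the wild source through the bottlenecked lineages;
the two lineages differentiate strongly (F<sub>ST</sub> ≈ 0.28) despite
sharing founders four generations back; genomic inbreeding
(F<sub>ROH</sub>, F<sub>H</sub>) rises with the pedigree coefficients; and
the ABBA-BABA test flags the planted donor gene flow into lineage 1 at
|Z| > 3 while the simulator's truth table confirms the admixed ancestry.

The same stages run from a shell:

```bash
founderpop run-all --simulate --seed 3 --out runs/demo
founderpop roh --vcf panel.vcf --out runs/roh
founderpop kmer --reads reads.fastq -k 17
```

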