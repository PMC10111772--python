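"""Deleterious-mutation load: a minimal coding-effect classifier (stop-gain /
stop-loss / start-loss / splice -> HIGH, missense -> MODERATE, synonymous ->
LOW), per-individual genotype accounting stratified by impact, the unfolded
derived-allele site-frequency spectrum, and the Rxy relative-load statistic.

Load analyses require polarized sites (the derived allele defined by the
outgroup); sites with unknown ancestral state are excluded and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_store import MISSING, GenotypeMatrix, PopulationSpec

logger = logging.getLogger(__name__)

CATEGORIES = ("HIGH", "MODERATE", "LOW")
_SEVERITY = {"HIGH": 3, "MODERATE": 2, "LOW": 1}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ----------------------------------------------------------------- classifier

def _translate(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


class _Transcript:
    """CDS model of one transcript: coding-order position map and sequence."""

    def __init__(self, seqid, strand, parts, reference):
        self.seqid = seqid
        self.strand = strand
        parts = sorted(parts, key=lambda p: p[0])  # genomic order (start, end, phase)
        self.genomic_parts = parts
        coding = parts if strand == "+" else parts[::-1]
        self.phase = int(coding[0][2] or 0)
        positions, bases = [], []
        for start, end, _ in coding:
            seq = str(reference[self.seqid][start - 1:end]).upper()
            pos = list(range(start, end + 1))
            if strand == "-":
                seq = seq.translate(_COMPLEMENT)[::-1]
                pos = pos[::-1]
            positions.extend(pos)
            bases.append(seq)
        self.coding_seq = "".join(bases)
        self.index = {p: i for i, p in enumerate(positions)}
        self.splice_positions = set()
        for (s1, e1, _), (s2, e2, _) in zip(parts, parts[1:]):
            if s2 - e1 > 1:  # real intron between consecutive CDS parts
                self.splice_positions.update(range(e1 + 1, min(e1 + 3, s2)))
                self.splice_positions.update(range(max(s2 - 2, e1 + 1), s2))

    def classify(self, pos: int, ref: str, alt: str) -> str | None:
        if pos in self.splice_positions:
            return "HIGH"
        idx = self.index.get(pos)
        if idx is None:
            return None
        if self.strand == "-":
            ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
        ci = (idx - self.phase) // 3
        if ci < 0:
            return None
        lo = self.phase + 3 * ci
        ref_codon = self.coding_seq[lo:lo + 3]
        if len(ref_codon) < 3:
            return None
        within = idx - lo
        alt_codon = ref_codon[:within] + alt + ref_codon[within + 1:]
        if ref_codon[within] != ref:
            return None  # caller checks reference concordance separately
        ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
        if ci == 0 and ref_codon == "ATG" and alt_codon != "ATG":
            return "HIGH"  # start-loss
        if alt_aa == "*" and ref_aa != "*":
            return "HIGH"  # stop-gain
        if ref_aa == "*" and alt_aa != "*":
            return "HIGH"  # stop-loss
        return "LOW" if ref_aa == alt_aa else "MODERATE"


def classify_effects(gm: GenotypeMatrix, gene_models, reference,
                     splice_window: int = 2) -> pd.Series:
    """Assign an impact category to every site (None outside coding regions).

    ``gene_models`` is a GFF3 path (CDS features with strand and phase);
    ``reference`` a FASTA path matching the VCF coordinates.  Sites whose REF
    allele disagrees with the reference sequence are excluded (None) with a
    warning.  Overlapping transcripts resolve by most-severe-effect-wins.
    """
    import gffutils
    from pyfaidx import Fasta

    if splice_window != 2:
        raise NotImplementedError("splice window is fixed at +-2 bp")
    fa = Fasta(str(reference), rebuild=False)
    db = gffutils.create_db(str(gene_models), ":memory:", keep_order=True,
                            merge_strategy="create_unique")
    by_parent: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parent = cds.attributes.get("Parent", [cds.id])[0]
        rec = by_parent.setdefault(parent, {"seqid": cds.seqid,
                                            "strand": cds.strand, "parts": []})
        rec["parts"].append((cds.start, cds.end,
                             cds.frame if cds.frame != "." else 0))
    transcripts = [_Transcript(r["seqid"], r["strand"], r["parts"], fa)
                   for r in by_parent.values()]
    by_chrom: dict[str, list[_Transcript]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.seqid, []).append(t)

    out = []
    n_mismatch = 0
    for row in gm.sites.itertuples(index=False):
        pos, ref, alt = int(row.pos), row.ref, row.alt
        if row.chrom in fa:
            genome_base = str(fa[row.chrom][pos - 1]).upper()
            if genome_base != ref:
                n_mismatch += 1
                out.append(None)
                continue
        best = None
        for t in by_chrom.get(row.chrom, []):
            cat = t.classify(pos, ref, alt)
            if cat and (best is None or _SEVERITY[cat] > _SEVERITY[best]):
                best = cat
        out.append(best)
    if n_mismatch:
        logger.warning("%d sites excluded: REF allele mismatches the reference "
                       "sequence", n_mismatch)
    return pd.Series(out, index=gm.sites.index, dtype=object, name="impact")


# ------------------------------------------------------------------ load table

@dataclass
class MutationLoadTable:
    """Impact-stratified derived-genotype accounting."""

    per_sample: pd.DataFrame        # sample, population, category, hom, het, hom_proportion
    population_means: pd.DataFrame  # population, category, mean_hom, mean_het, mean_hom_proportion
    t_tests: pd.DataFrame           # category, pop_a, pop_b, t, p  (Welch, on hom counts)
    n_unpolarized_excluded: int


def load_table(gm: GenotypeMatrix, categories: pd.Series | np.ndarray,
               spec: PopulationSpec, populations=None) -> MutationLoadTable:
    """Per-sample homozygous/heterozygous derived counts per impact category.

    ``hom`` counts derived dosage 2 and ``het`` dosage 1;
    ``hom_proportion = hom / (hom + het)``.  Population means are compared
    between all population pairs per category with Welch's unequal-variance
    t-test on the per-sample hom counts.
    """
    from scipy import stats

    cats = np.asarray(pd.Series(categories, dtype=object))
    polarized = gm.polarized_mask
    n_excluded = int((~polarized & pd.notna(cats)).sum())
    pops = populations or spec.ingroup_populations
    rows = []
    for pop in pops:
        samples = spec.samples_in(pop)
        d = gm.derived_dosage(samples)
        for cat in CATEGORIES:
            mask = polarized & (cats == cat)
            sub = d[:, mask]
            hom = (sub == 2).sum(axis=1)
            het = (sub == 1).sum(axis=1)
            for s, ho, he in zip(samples, hom, het):
                tot = int(ho + he)
                rows.append({"sample": s, "population": pop, "category": cat,
                             "hom": int(ho), "het": int(he),
                             "hom_proportion": ho / tot if tot else np.nan})
    per_sample = pd.DataFrame(rows)
    means = (per_sample.groupby(["population", "category"], sort=False)
             .agg(mean_hom=("hom", "mean"), mean_het=("het", "mean"),
                  mean_hom_proportion=("hom_proportion", "mean"))
             .reset_index())
    t_rows = []
    for cat in CATEGORIES:
        sub = per_sample[per_sample["category"] == cat]
        for i, pa in enumerate(pops):
            for pb in pops[i + 1:]:
                xa = sub.loc[sub["population"] == pa, "hom"]
                xb = sub.loc[sub["population"] == pb, "hom"]
                if len(xa) < 2 or len(xb) < 2:
                    t, p = np.nan, np.nan
                else:
                    t, p = stats.ttest_ind(xa, xb, equal_var=False)
                t_rows.append({"category": cat, "pop_a": pa, "pop_b": pb,
                               "t": t, "p": p})
    return MutationLoadTable(per_sample, means, pd.DataFrame(t_rows), n_excluded)


# ------------------------------------------------------------------------- SFS

@dataclass
class SFS:
    """Unfolded site-frequency spectrum for one category and population.

    ``spectrum[i]`` is the (possibly fractional, if projected) number of
    polymorphic sites with derived-allele count ``i``; classes 0 and
    ``n_copies`` are excluded.
    """

    category: str
    n_copies: int
    spectrum: np.ndarray  # length n_copies + 1; entries 0 and n are zero
    n_excluded: int       # sites dropped (unpolarized, uncalled, or below target n)

    @property
    def total_sites(self) -> float:
        return float(self.spectrum.sum())

    def binned(self, threshold: int = 10, width: int = 10) -> pd.DataFrame:
        """Display binning: counts below ``threshold`` individually; counts at
        or above it summarized as the mean number of sites per count class
        within consecutive intervals of ``width`` classes."""
        rows = [{"bin": str(i), "sites": float(self.spectrum[i])}
                for i in range(1, min(threshold, self.n_copies))]
        lo = threshold
        while lo < self.n_copies:
            hi = min(lo + width - 1, self.n_copies - 1)
            vals = self.spectrum[lo:hi + 1]
            rows.append({"bin": f"{lo}-{hi}", "sites": float(vals.mean())})
            lo = hi + 1
        return pd.DataFrame(rows)


def _hypergeometric_projection(j: int, n_from: int, n_to: int) -> np.ndarray:
    """P(k derived among n_to sampled copies | j of n_from copies derived)."""
    from scipy.stats import hypergeom

    k = np.arange(n_to + 1)
    return hypergeom.pmf(k, n_from, j, n_to)


def sfs(gm: GenotypeMatrix, categories, population: str, spec: PopulationSpec,
        category: str, n_copies: int | None = None,
        deviating: str = "project") -> SFS:
    """Unfolded derived-allele SFS for one impact category in one population.

    Sites with more called copies than the target are projected down
    hypergeometrically (``deviating="project"``) or dropped
    (``deviating="exclude"``); sites with fewer are always dropped.  The
    target ``n_copies`` defaults to the modal called-copy count.
    """
    cats = np.asarray(pd.Series(categories, dtype=object))
    samples = spec.samples_in(population)
    d = gm.derived_dosage(samples)
    mask = gm.polarized_mask & (cats == category)
    d = d[:, mask]
    called = d != MISSING
    n = 2 * called.sum(axis=0)
    j = np.where(called, d, 0).sum(axis=0)
    if n_copies is None:
        valid = n[n > 0]
        if valid.size == 0:
            return SFS(category, 0, np.zeros(1), int(mask.sum()))
        n_copies = int(np.bincount(valid).argmax())
    spectrum = np.zeros(n_copies + 1)
    n_excluded = 0
    for ji, ni in zip(j, n):
        if ni < n_copies or ni == 0:
            n_excluded += 1
            continue
        if ni == n_copies:
            if 0 < ji < ni:
                spectrum[ji] += 1.0
        elif deviating == "project":
            probs = _hypergeometric_projection(int(ji), int(ni), n_copies)
            spectrum[1:n_copies] += probs[1:n_copies]
        else:
            n_excluded += 1
    return SFS(category, n_copies, spectrum, n_excluded)


# ------------------------------------------------------------------------- Rxy

@dataclass
class RxyResult:
    """Relative derived-allele load of category sites in X versus Y.

    ``Rxy < 1`` indicates a relative frequency deficit of the category in X.
    """

    pop_x: str
    pop_y: str
    category: str
    l_x_not_y: float
    l_y_not_x: float
    rxy: float
    ci_low: float
    ci_high: float
    n_sites: int
    n_blocks: int
    normalized_by_low: bool = False


def rxy(gm: GenotypeMatrix, categories, pop_x: str, pop_y: str,
        spec: PopulationSpec, category: str,
        normalize_by_low: bool = False) -> RxyResult:
    """Rxy = L(X not Y) / L(Y not X) over the category's polarized sites,
    where ``L(X not Y) = sum_i dX_i (1 - dY_i)`` with dX, dY the derived
    frequencies.  The CI comes from a delete-one-chromosome jackknife.
    With ``normalize_by_low`` the same ratio computed on LOW sites divides
    the category ratio (neutral-standardized Rxy).
    """
    cats = np.asarray(pd.Series(categories, dtype=object))
    dx = gm.derived_frequency(spec.samples_in(pop_x))
    dy = gm.derived_frequency(spec.samples_in(pop_y))
    chroms = gm.sites["chrom"].to_numpy()

    def terms(cat):
        mask = gm.polarized_mask & (cats == cat) & np.isfinite(dx) & np.isfinite(dy)
        return dx[mask] * (1 - dy[mask]), dy[mask] * (1 - dx[mask]), chroms[mask]

    num, den, site_chrom = terms(category)
    if den.sum() == 0:
        return RxyResult(pop_x, pop_y, category, float(num.sum()), 0.0,
                         float("nan"), float("nan"), float("nan"),
                         int(len(num)), 0, normalize_by_low)
    ratio = float(num.sum() / den.sum())
    norm = 1.0
    if normalize_by_low:
        lnum, lden, _ = terms("LOW")
        if lden.sum() > 0 and lnum.sum() > 0:
            norm = float(lnum.sum() / lden.sum())
    est = ratio / norm
    blocks = pd.unique(site_chrom)
    loo = []
    for c in blocks:
        keep = site_chrom != c
        d = den[keep].sum()
        if d > 0:
            loo.append(num[keep].sum() / d / norm)
    loo = np.asarray(loo)
    if len(loo) >= 2:
        g = len(loo)
        se = float(np.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum()))
        ci = (est - 1.96 * se, est + 1.96 * se)
    else:
        ci = (float("nan"), float("nan"))
    return RxyResult(pop_x, pop_y, category, float(num.sum()), float(den.sum()),
                     est, ci[0], ci[1], int(len(num)), len(loo), normalize_by_low)
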