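"""Runs of homozygosity (sliding-window scanner), F_ROH by length class, and
the excess-homozygosity inbreeding coefficient F_H.

The ROH scanner follows the PLINK ``--homozyg`` algorithm: 100-SNP windows
slide one SNP at a time along a chromosome; a window is called homozygous if
it contains at most ``window_het`` heterozygous and ``window_missing`` missing
calls; each SNP's hit rate is the fraction of windows containing it that are
homozygous; SNPs at or above the hit-rate threshold form candidate runs, which
are split at large inter-SNP gaps and kept if they satisfy the SNP-count,
length, and density minima.  There is no segment-level heterozygote cap
(only the window-level allowance applies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_store import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: F_ROH length-class thresholds in bp (>=100 kb, >=1 Mb, >=2 Mb)
LENGTH_THRESHOLDS = {"100kb": 100_000, "1Mb": 1_000_000, "2Mb": 2_000_000}


@dataclass(frozen=True)
class ROHParams:
    """Scanner parameters (defaults mirror PLINK ``--homozyg`` settings
    commonly used for mammal re-sequencing panels)."""

    window_snp: int = 100
    window_het: int = 2
    window_missing: int = 5
    min_snp: int = 100
    min_kb: float = 100.0
    density_kb: float = 10.0     # at least one SNP per this many kb on average
    max_gap_kb: float = 100.0
    window_hit_threshold: float = 0.05

    def __post_init__(self):
        if not 0 < self.window_hit_threshold <= 1:
            raise ValueError("window_hit_threshold must be in (0, 1]")
        if min(self.window_snp, self.window_het + 1, self.window_missing + 1,
               self.min_snp) <= 0 or min(self.min_kb, self.density_kb,
                                         self.max_gap_kb) <= 0:
            raise ValueError("ROH parameters must be positive")


ROH_COLUMNS = ["sample", "chrom", "start", "end", "n_snps", "length",
               "length_class"]


def _length_class(length: int) -> str:
    if length > 2_000_000:
        return ">2Mb"
    if length > 1_000_000:
        return "1-2Mb"
    return "100kb-1Mb"


def _moving_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def detect_roh(gm: GenotypeMatrix, sample: str,
               params: ROHParams = ROHParams()) -> pd.DataFrame:
    """Detect ROH segments for one sample; returns one row per segment
    (``start``/``end`` are the 1-based positions of the first and last SNP,
    length = end - start + 1)."""
    si = gm.sample_index(sample)
    geno = gm.genotypes[si]
    chroms = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        cpos = pos[mask]
        g = geno[mask]
        order = np.argsort(cpos)
        cpos, g = cpos[order], g[order]
        n = len(cpos)
        w = params.window_snp
        if n < w:
            logger.info("chromosome %s has %d < %d SNPs; no ROH calls",
                        chrom, n, w)
            continue
        het = (g == 1).astype(np.int64)
        mis = (g == MISSING).astype(np.int64)
        hom_window = (_moving_sum(het, w) <= params.window_het) \
            & (_moving_sum(mis, w) <= params.window_missing)
        # hit rate per SNP over the windows that contain it
        n_windows = n - w + 1
        cum_hom = np.concatenate([[0], np.cumsum(hom_window)])
        t = np.arange(n)
        first = np.maximum(t - w + 1, 0)
        last = np.minimum(t, n_windows - 1)
        containing = last - first + 1
        hits = cum_hom[last + 1] - cum_hom[first]
        passing = hits / containing >= params.window_hit_threshold

        # maximal passing stretches, split at large gaps
        idx = np.flatnonzero(passing)
        if idx.size == 0:
            continue
        gap_split = np.diff(cpos[idx]) > params.max_gap_kb * 1000.0
        breaks = np.flatnonzero((np.diff(idx) > 1) | gap_split)
        for seg in np.split(idx, breaks + 1):
            n_snps = seg.size
            start, end = int(cpos[seg[0]]), int(cpos[seg[-1]])
            length = end - start + 1
            if n_snps < params.min_snp or length < params.min_kb * 1000.0:
                continue
            if length / n_snps > params.density_kb * 1000.0:
                continue
            rows.append({"sample": sample, "chrom": chrom, "start": start,
                         "end": end, "n_snps": n_snps, "length": length,
                         "length_class": _length_class(length)})
    return pd.DataFrame(rows, columns=ROH_COLUMNS)


def detect_roh_all(gm: GenotypeMatrix, params: ROHParams = ROHParams(),
                   samples=None) -> pd.DataFrame:
    frames = [detect_roh(gm, s, params) for s in (samples or gm.samples)]
    return pd.concat(frames, ignore_index=True) if frames \
        else pd.DataFrame(columns=ROH_COLUMNS)


def f_roh(segments: pd.DataFrame, genome_length: int,
          min_length: int = 100_000) -> float:
    """Fraction of the genome in ROH at least ``min_length`` bp long."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if segments.empty:
        return 0.0
    keep = segments["length"] >= min_length
    return float(segments.loc[keep, "length"].sum() / genome_length)


def f_h(gm: GenotypeMatrix, sample: str) -> float:
    """Excess-homozygosity inbreeding coefficient.

    ``F_H = (O_hom - E_hom) / (N - E_hom)`` where ``O_hom`` is the sample's
    observed homozygous-site count, ``N`` its called-site count, and
    ``E_hom = sum_i (1 - 2 p_i q_i n_i/(n_i - 1))`` the Hardy-Weinberg
    expectation from cohort allele frequencies ``p_i`` (with the usual
    small-sample correction; ``n_i`` = called allele copies in the cohort).
    """
    si = gm.sample_index(sample)
    g = gm.genotypes[si]
    called = g != MISSING
    alt, n = gm.allele_counts()
    use = called & (n >= 2)
    if not use.any():
        return float("nan")
    p = alt[use] / n[use]
    nf = n[use].astype(float)
    e_hom = float(np.sum(1.0 - 2.0 * p * (1.0 - p) * nf / (nf - 1.0)))
    o_hom = float(((g[use] == 0) | (g[use] == 2)).sum())
    n_called = float(use.sum())
    denom = n_called - e_hom
    return (o_hom - e_hom) / denom if denom != 0 else float("nan")


def inbreeding_table(gm: GenotypeMatrix, segments: pd.DataFrame,
                     genome_length: int | None = None,
                     samples=None) -> pd.DataFrame:
    """Per-sample inbreeding summary: F_H, F_ROH at the 100 kb / 1 Mb / 2 Mb
    thresholds, and ROH counts and summed lengths per length class.

    ``genome_length`` defaults to the sum of contig lengths carried by the
    matrix (configurable for comparability across panels).
    """
    if genome_length is None:
        genome_length = sum(gm.contig_lengths.values())
        if genome_length <= 0:
            raise ValueError("no contig lengths available; pass genome_length")
    rows = []
    for sample in samples or gm.samples:
        seg = segments[segments["sample"] == sample]
        row = {"sample": sample, "F_H": f_h(gm, sample),
               "genome_length": genome_length,
               "n_roh": int(len(seg)), "roh_total_bp": int(seg["length"].sum())}
        for label, thr in LENGTH_THRESHOLDS.items():
            row[f"F_ROH_{label}"] = f_roh(seg, genome_length, thr)
        for cls in ("100kb-1Mb", "1-2Mb", ">2Mb"):
            sub = seg[seg["length_class"] == cls]
            row[f"n_roh_{cls}"] = int(len(sub))
            row[f"bp_roh_{cls}"] = int(sub["length"].sum())
        rows.append(row)
    return pd.DataFrame(rows)
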