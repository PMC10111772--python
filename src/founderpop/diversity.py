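"""Genetic diversity: per-individual heterozygosity, sliding-window nucleotide
diversity (pi) and Watterson's theta, and Weir-Cockerham / Hudson FST.

Windows tile each chromosome from position 0 in fixed steps; the trailing
partial window keeps its true span.  Window statistics are divided by the full
window span in bp (the common windowed-diversity convention), not by the count
of callable sites; pass ``denominator="sites"`` for the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_store import MISSING, GenotypeMatrix, PopulationSpec


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in bp (default 20 kb windows, 10 kb steps)."""

    length: int = 20_000
    step: int = 10_000

    def __post_init__(self):
        if self.length <= 0 or self.step <= 0 or self.step > self.length:
            raise ValueError("need 0 < step <= length")


def individual_heterozygosity(gm: GenotypeMatrix, sample: str,
                              callable_length: int | None = None) -> float:
    """Proportion of heterozygous genotypes among a sample's called genotypes.

    With ``callable_length`` the count of heterozygous sites is instead divided
    by that genome length (per-bp heterozygosity).  Returns NaN when the sample
    has no called genotypes.
    """
    g = gm.genotypes[gm.sample_index(sample)]
    called = g != MISSING
    n_het = int((g == 1).sum())
    if callable_length is not None:
        return n_het / callable_length
    n_called = int(called.sum())
    return n_het / n_called if n_called else float("nan")


def _chrom_length(gm: GenotypeMatrix, chrom: str, pos: np.ndarray) -> int:
    return int(gm.contig_lengths.get(chrom, pos.max()))


def _window_starts(chrom_length: int, w: WindowSpec) -> np.ndarray:
    return np.arange(0, max(chrom_length, 1), w.step)


def _per_site_stats(gm: GenotypeMatrix, samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (pi_i, segregating flag, 1/a_n contribution) over a sample set."""
    alt, n = gm.allele_counts(samples)
    usable = n >= 2
    j = alt.astype(float)
    nf = n.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(usable, 2.0 * j * (nf - j) / (nf * (nf - 1.0)), 0.0)
    seg = usable & (alt > 0) & (alt < n)
    # Watterson: each segregating site contributes 1/a_n with its own n
    harmonic = np.zeros_like(nf)
    max_n = int(n.max()) if len(n) else 0
    if max_n >= 2:
        cum = np.concatenate([[0.0, 0.0], np.cumsum(1.0 / np.arange(1, max_n))])
        harmonic = cum[np.minimum(n, max_n)]
    with np.errstate(divide="ignore"):
        inv_an = np.where(seg & (harmonic > 0), 1.0 / np.maximum(harmonic, 1e-300), 0.0)
    return pi, seg, inv_an


def diversity_windows(gm: GenotypeMatrix, population: str | None = None,
                      spec: PopulationSpec | None = None,
                      window: WindowSpec = WindowSpec(),
                      samples=None) -> pd.DataFrame:
    """Sliding-window pi and Watterson's theta for one population.

    Returns a frame with one row per window: ``chrom, start, end, span,
    n_sites, S, pi, theta_w`` (start/end 0-based half-open; pi and theta_w
    are per-bp over the window span).
    """
    if samples is None:
        if population is None or spec is None:
            raise ValueError("pass either samples or (population, spec)")
        samples = spec.samples_in(population)
    pi_site, seg, inv_an = _per_site_stats(gm, samples)
    pos0 = gm.sites["pos"].to_numpy() - 1
    chroms = gm.sites["chrom"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        cpos = pos0[mask]
        clen = _chrom_length(gm, chrom, cpos + 1)
        order = np.argsort(cpos)
        cpos, cpi, cseg, cinv = cpos[order], pi_site[mask][order], \
            seg[mask][order], inv_an[mask][order]
        cum_pi = np.concatenate([[0.0], np.cumsum(cpi)])
        cum_s = np.concatenate([[0], np.cumsum(cseg)])
        cum_inv = np.concatenate([[0.0], np.cumsum(cinv)])
        for start in _window_starts(clen, window):
            end = min(start + window.length, clen)
            lo = np.searchsorted(cpos, start, side="left")
            hi = np.searchsorted(cpos, end, side="left")
            span = end - start
            rows.append({
                "chrom": chrom, "start": int(start), "end": int(end),
                "span": int(span), "n_sites": int(hi - lo),
                "S": int(cum_s[hi] - cum_s[lo]),
                "pi": (cum_pi[hi] - cum_pi[lo]) / span,
                "theta_w": (cum_inv[hi] - cum_inv[lo]) / span,
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "span",
                                       "n_sites", "S", "pi", "theta_w"])


def windowed_pi(gm, population=None, spec=None, window=WindowSpec(), samples=None):
    """Sliding-window nucleotide diversity; see :func:`diversity_windows`."""
    return diversity_windows(gm, population, spec, window, samples)[
        ["chrom", "start", "end", "span", "n_sites", "S", "pi"]]


def windowed_theta_w(gm, population=None, spec=None, window=WindowSpec(), samples=None):
    """Sliding-window Watterson's theta; see :func:`diversity_windows`."""
    return diversity_windows(gm, population, spec, window, samples)[
        ["chrom", "start", "end", "span", "n_sites", "S", "theta_w"]]


def mean_pi(gm: GenotypeMatrix, samples) -> float:
    """Genome-wide per-bp pi over the full genome length (contig headers)."""
    pi_site, _, _ = _per_site_stats(gm, samples)
    total_len = sum(gm.contig_lengths.values()) or int(gm.sites["pos"].max())
    return float(pi_site.sum() / total_len)


# ------------------------------------------------------------------------- FST

def _wc84_components(gm: GenotypeMatrix, samples_a, samples_b
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components a, b, c for two
    populations, from genotype counts."""
    comps = []
    for samples in (samples_a, samples_b):
        g = gm.genotypes[gm.sample_indices(samples)]
        called = g != MISSING
        n = called.sum(axis=0).astype(float)            # diploids called
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, g, 0).sum(axis=0) / np.maximum(2 * n, 1)
            h = (g == 1).sum(axis=0) / np.maximum(n, 1)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nbar = (n1 + n2) / r
    ok = (n1 >= 1) & (n2 >= 1) & (nbar > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    zero = ~ok | ~np.isfinite(a) | ~np.isfinite(b) | ~np.isfinite(c)
    a = np.where(zero, 0.0, a)
    b = np.where(zero, 0.0, b)
    c = np.where(zero, 0.0, c)
    return a, b, c


def _hudson_components(gm: GenotypeMatrix, samples_a, samples_b
                       ) -> tuple[np.ndarray, np.ndarray]:
    comps = []
    for samples in (samples_a, samples_b):
        alt, n = gm.allele_counts(samples)
        comps.append((alt.astype(float), n.astype(float)))
    (j1, n1), (j2, n2) = comps
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = j1 / np.maximum(n1, 1), j2 / np.maximum(n2, 1)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / np.maximum(n1 - 1, 1) \
            - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return np.where(ok, num, 0.0), np.where(ok, den, 0.0)


@dataclass
class FstResult:
    """Pairwise FST between two populations."""

    fst: float                 # genome-wide ratio-of-averages ("weighted")
    mean_of_ratios: float      # mean of per-window ratios
    windows: pd.DataFrame      # chrom, start, end, fst
    estimator: str

    @property
    def window_sd(self) -> float:
        vals = self.windows["fst"].dropna()
        return float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")


def pairwise_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str,
                 spec: PopulationSpec, window: WindowSpec = WindowSpec(),
                 estimator: str = "wc84") -> FstResult:
    """Pairwise FST with per-window values.

    ``estimator`` is ``"wc84"`` (Weir & Cockerham 1984 variance components;
    genome-wide value is the ratio of summed components, i.e. "weighted" FST)
    or ``"hudson"``.  Negative per-window estimates are reported as computed.
    Returns NaN when every site is monomorphic across both populations.
    """
    sa, sb = spec.samples_in(pop_a), spec.samples_in(pop_b)
    if estimator == "wc84":
        a, b, c = _wc84_components(gm, sa, sb)
        num, den = a, a + b + c
    elif estimator == "hudson":
        num, den = _hudson_components(gm, sa, sb)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    pos0 = gm.sites["pos"].to_numpy() - 1
    chroms = gm.sites["chrom"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        cpos = pos0[mask]
        clen = _chrom_length(gm, chrom, cpos + 1)
        order = np.argsort(cpos)
        cpos, cn, cd = cpos[order], num[mask][order], den[mask][order]
        cum_n = np.concatenate([[0.0], np.cumsum(cn)])
        cum_d = np.concatenate([[0.0], np.cumsum(cd)])
        for start in _window_starts(clen, window):
            end = min(start + window.length, clen)
            lo = np.searchsorted(cpos, start, side="left")
            hi = np.searchsorted(cpos, end, side="left")
            wd = cum_d[hi] - cum_d[lo]
            rows.append({"chrom": chrom, "start": int(start), "end": int(end),
                         "fst": (cum_n[hi] - cum_n[lo]) / wd if wd > 0 else np.nan})
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "fst"])
    total_den = float(den.sum())
    fst = float(num.sum() / total_den) if total_den > 0 else float("nan")
    ratios = windows["fst"].dropna()
    return FstResult(fst, float(ratios.mean()) if len(ratios) else float("nan"),
                     windows, estimator)


def fst_matrix(gm: GenotypeMatrix, spec: PopulationSpec,
               window: WindowSpec = WindowSpec(),
               estimator: str = "wc84") -> pd.DataFrame:
    """Square population matrix: weighted FST above the diagonal, the standard
    deviation of per-window FST below, zeros on the diagonal."""
    pops = spec.ingroup_populations
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        for pb in pops[i + 1:]:
            res = pairwise_fst(gm, pa, pb, spec, window, estimator)
            mat.loc[pa, pb] = res.fst
            mat.loc[pb, pa] = res.window_sd
    return mat
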