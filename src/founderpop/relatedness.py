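"""Pairwise relatedness and phylogeny from SNP dosages: IBS identity,
p-distance, method-of-moments IBD sharing (Z0/Z1/Z2, PI_HAT), genotype PCA,
neighbor-joining trees, and site-bootstrap branch support.

Distances use the standard biallelic shared-allele convention: for dosages
``d_i, d_j`` the pairwise identity at a site is ``(2 - |d_i - d_j|) / 2``, so
the p-distance is the mean of ``|d_i - d_j| / 2`` over co-called sites and
equals one minus the IBS identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .variant_store import MISSING, GenotypeMatrix


# ------------------------------------------------------------------- distances

def p_distance_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise p-distance: mean |dosage difference| / 2 over co-called sites.

    Entries with no co-called sites are NaN.
    """
    n = gm.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    g = gm.genotypes.astype(float)
    g[gm.genotypes == MISSING] = np.nan
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g - g[i]) / 2.0
        cnt = (~np.isnan(diff)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[i] = np.where(cnt > 0, np.nansum(diff, axis=1)
                              / np.maximum(cnt, 1), np.nan)
        out[i, i] = 0.0
    return pd.DataFrame(out, index=gm.samples, columns=gm.samples)


def ibs_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """IBS distance matrix: 1 - mean pairwise identity (= the p-distance)."""
    return p_distance_matrix(gm)


def write_phylip(dm: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for name in dm.index:
            vals = " ".join(f"{v:.6f}" for v in dm.loc[name])
            fh.write(f"{name}  {vals}\n")


# ---------------------------------------------------------------- IBD (moments)

@dataclass
class IBDResult:
    """Method-of-moments IBD sharing for every sample pair."""

    table: pd.DataFrame  # sample_1, sample_2, Z0, Z1, Z2, PI_HAT, n_sites,
    #                      low_confidence, above_min

    def pair(self, a: str, b: str) -> pd.Series:
        t = self.table
        hit = t[((t.sample_1 == a) & (t.sample_2 == b))
                | ((t.sample_1 == b) & (t.sample_2 == a))]
        if hit.empty:
            raise KeyError((a, b))
        return hit.iloc[0]


def _expected_ibs_given_ibd(alt: np.ndarray, n: np.ndarray):
    """Per-site expected IBS-state probabilities given IBD state, with the
    standard small-sample corrections from sample allele frequencies."""
    a = n.astype(float)
    p = np.where(a > 0, alt / np.maximum(a, 1), np.nan)
    q = 1.0 - p
    x, y = p * a, q * a
    ok = (a >= 4) & (alt > 0) & (alt < n)
    with np.errstate(invalid="ignore", divide="ignore"):
        c3 = a / (a - 1) * a / (a - 2) * a / (a - 3)
        c2 = a / (a - 1) * a / (a - 2)
        e00 = 2 * p * p * q * q * ((x - 1) / x) * ((y - 1) / y) * c3
        e10 = 4 * p ** 3 * q * ((x - 1) / x) * ((x - 2) / x) * c3 \
            + 4 * p * q ** 3 * ((y - 1) / y) * ((y - 2) / y) * c3
        e20 = q ** 4 * ((y - 1) / y) * ((y - 2) / y) * ((y - 3) / y) * c3 \
            + p ** 4 * ((x - 1) / x) * ((x - 2) / x) * ((x - 3) / x) * c3 \
            + 4 * p * p * q * q * ((x - 1) / x) * ((y - 1) / y) * c3
        e11 = 2 * p * p * q * ((x - 1) / x) * c2 + 2 * p * q * q * ((y - 1) / y) * c2
        e21 = p ** 3 * ((x - 1) / x) * ((x - 2) / x) * c2 \
            + q ** 3 * ((y - 1) / y) * ((y - 2) / y) * c2 \
            + p * p * q * ((x - 1) / x) * c2 + p * q * q * ((y - 1) / y) * c2
    es = [np.where(ok, e, 0.0) for e in (e00, e10, e20, e11, e21)]
    return es, ok


def ibd_moments(gm: GenotypeMatrix, min_pi_hat: float = 0.05,
                min_informative: int = 50, samples=None) -> IBDResult:
    """PLINK-style method-of-moments IBD estimates for all sample pairs.

    Allele frequencies come from the full sample set (including the pair),
    with small-sample corrections; Z estimates are bounded to [0, 1] and
    renormalized.  Every pair is reported; ``above_min`` flags pairs with
    ``PI_HAT >= min_pi_hat`` and ``low_confidence`` flags pairs with fewer
    than ``min_informative`` informative co-called sites.
    """
    alt, n = gm.allele_counts()
    (e00, e10, e20, e11, e21), informative = _expected_ibs_given_ibd(alt, n)
    use = gm if samples is None else gm.take_samples(samples)
    g = use.genotypes
    called = g != MISSING
    rows = []
    for i in range(use.n_samples):
        for j in range(i + 1, use.n_samples):
            mask = called[i] & called[j] & informative
            cnt = int(mask.sum())
            diff = np.abs(g[i, mask].astype(int) - g[j, mask].astype(int))
            o0, o1 = float((diff == 2).sum()), float((diff == 1).sum())
            o2 = float(cnt) - o0 - o1
            n00, n10, n20 = e00[mask].sum(), e10[mask].sum(), e20[mask].sum()
            n11, n21 = e11[mask].sum(), e21[mask].sum()
            if cnt == 0 or n00 <= 0 or n11 <= 0:
                z0 = z1 = z2 = np.nan
            else:
                z0 = o0 / n00
                z1 = (o1 - z0 * n10) / n11
                z2 = (o2 - z0 * n20 - z1 * n21) / cnt
                z0, z1, z2 = (min(max(z, 0.0), 1.0) for z in (z0, z1, z2))
                total = z0 + z1 + z2
                if total > 0:
                    z0, z1, z2 = z0 / total, z1 / total, z2 / total
            pi_hat = z1 / 2.0 + z2 if cnt else np.nan
            rows.append({"sample_1": use.samples[i], "sample_2": use.samples[j],
                         "Z0": z0, "Z1": z1, "Z2": z2, "PI_HAT": pi_hat,
                         "n_sites": cnt,
                         "low_confidence": cnt < min_informative,
                         "above_min": bool(pi_hat >= min_pi_hat) if cnt else False})
    return IBDResult(pd.DataFrame(rows))


# ------------------------------------------------------------------------- PCA

@dataclass
class PCAResult:
    coordinates: pd.DataFrame    # samples x PCs
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def genotype_pca(gm: GenotypeMatrix, k: int = 2) -> PCAResult:
    """PCA of the dosage matrix with EIGENSTRAT-style scaling.

    Missing dosages are mean-imputed; each site is centered by ``2*p`` and
    scaled by ``sqrt(2*p*(1-p))`` with ``p`` the sample ALT frequency;
    monomorphic sites are dropped.  Coordinates are deterministic up to the
    fixed sign convention (largest-magnitude loading positive).
    """
    g = gm.genotypes.astype(float)
    g[gm.genotypes == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    variable = (p > 0) & (p < 1)
    if not variable.any():
        raise ValueError("no variable sites for PCA")
    g = g[:, variable]
    p = p[variable]
    if g.shape[0] < 2 or g.shape[1] < k:
        raise ValueError("need >= 2 samples and >= k variable sites")
    g = np.where(np.isnan(g), 2 * p, g)
    x = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    x -= x.mean(axis=0)  # column-centering after imputation
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :k] * s[:k]
    for c in range(k):  # sign convention
        imax = np.argmax(np.abs(coords[:, c]))
        if coords[imax, c] < 0:
            coords[:, c] = -coords[:, c]
    ev = s ** 2 / (x.shape[0] - 1)
    total = ev.sum()
    return PCAResult(
        pd.DataFrame(coords, index=gm.samples,
                     columns=[f"PC{i + 1}" for i in range(k)]),
        ev[:k], ev[:k] / total)


# -------------------------------------------------------------- neighbor joining

def nj_tree(dm: pd.DataFrame, outgroup: str | None = None) -> TreeNode:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Negative branch lengths are clamped to zero with the deficit moved onto
    the sibling edge.  The returned tree is unrooted (trifurcating root)
    unless ``outgroup`` is given, in which case it is rooted on the edge
    leading to that sample for display.
    """
    if dm.isna().any().any():
        bad = [(r, c) for r in dm.index for c in dm.columns if pd.isna(dm.loc[r, c])]
        raise ValueError(f"distance matrix has missing entries: {bad[:5]}")
    names = list(dm.index)
    if len(names) < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.to_numpy(dtype=float).copy()
    nodes = [TreeNode(name=n) for n in names]
    active = list(range(len(names)))

    def clamp(li, lj):
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = TreeNode()
        nodes[i].length, nodes[j].length = float(li), float(lj)
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, dnew])
        d = np.hstack([d, np.append(dnew, 0.0)[:, None]])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    root = TreeNode()
    if len(active) == 3:
        i, j, k = active
        li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
        lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
        lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        for idx, ln in zip((i, j, k), (li, lj, lk)):
            nodes[idx].length = float(max(ln, 0.0))
            root.append(nodes[idx])
    else:  # exactly the 3-taxon entry case never leaves 2, but guard anyway
        i, j = active
        nodes[i].length = float(d[i, j] / 2.0)
        nodes[j].length = float(d[i, j] / 2.0)
        root.extend([nodes[i], nodes[j]])

    if outgroup is not None:
        root = root_at_outgroup(root, outgroup)
    return root


def root_at_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root a tree on the edge leading to the outgroup tip (for display)."""
    tip = tree.find(outgroup)
    try:
        return tree.root_at(tip, above=True, reset=True)
    except TypeError:  # older scikit-bio signatures
        return tree.root_at(tip.parent)


# -------------------------------------------------------------------- bootstrap

def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets normalized to exclude a fixed
    reference tip (the lexicographically smallest name)."""
    tips = sorted(t.name for t in tree.tips())
    ref = tips[0]
    full = frozenset(tips)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        parts.add(side if ref not in side else full - side)
    return parts


def bootstrap_support(gm: GenotypeMatrix, n_reps: int = 100, seed: int = 0,
                      outgroup: str | None = None, block_size: int | None = None,
                      distance=p_distance_matrix,
                      ) -> tuple[TreeNode, dict[frozenset, float]]:
    """Neighbor-joining tree with site-bootstrap branch support.

    Sites are resampled with replacement (``block_size`` switches to a block
    bootstrap over consecutive site blocks), the distance matrix and NJ tree
    are rebuilt per replicate, and each internal bipartition of the reference
    tree receives the fraction of replicates containing it.  Supports are
    written onto the internal nodes' names of the returned tree.
    """
    rng = np.random.default_rng(seed)
    ref_tree = nj_tree(distance(gm), outgroup=outgroup)
    ref_parts = _bipartitions(ref_tree)
    counts = {p: 0 for p in ref_parts}
    n_sites = gm.n_sites
    for _ in range(n_reps):
        if block_size:
            n_blocks = max(n_sites // block_size, 1)
            starts = rng.integers(0, n_blocks, size=n_blocks) * block_size
            idx = np.concatenate([np.arange(s, min(s + block_size, n_sites))
                                  for s in starts])
        else:
            idx = rng.integers(0, n_sites, size=n_sites)
        idx = np.sort(idx)
        boot = GenotypeMatrix(
            gm.samples,
            gm.sites.iloc[idx].assign(pos=np.arange(1, len(idx) + 1)),
            gm.genotypes[:, idx], contig_lengths=gm.contig_lengths)
        parts = _bipartitions(nj_tree(distance(boot)))
        for p in ref_parts & parts:
            counts[p] += 1
    support = {p: c / n_reps for p, c in counts.items()}
    for node in ref_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        tips = sorted(t.name for t in ref_tree.tips())
        key = side if tips[0] not in side else frozenset(tips) - side
        if key in support:
            node.name = f"{support[key]:g}"
    return ref_tree, support
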