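"""Frequency-based introgression statistics: Patterson's D (ABBA-BABA) with
delete-one block-jackknife significance, f4 and f4-ratio admixture
proportions, and per-individual mean introgression ratios with BH-FDR
filtering.

All statistics work on derived-allele frequencies, so the matrix must be
polarized first (see :func:`founderpop.variant_store.polarize_by_outgroup`).
Group labels passed to these functions may be population labels from the
:class:`~founderpop.variant_store.PopulationSpec` or individual sample ids
(treated as singleton populations), matching how admixture is tested per
individual against candidate donor subspecies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variant_store import GenotypeMatrix, PopulationSpec

DEFAULT_BLOCK_SIZE = 1000  # sites per jackknife block


def _resolve(spec: PopulationSpec, label: str) -> list[str]:
    if label in spec.mapping.values():
        return spec.samples_in(label)
    if label in spec.mapping:
        return [label]
    raise KeyError(f"{label!r} is neither a population nor a sample")


def _derived_freqs(gm: GenotypeMatrix, spec: PopulationSpec,
                   labels) -> tuple[np.ndarray, np.ndarray]:
    """Stacked derived-frequency rows for each label and the joint mask of
    sites where every group has a defined frequency."""
    freqs = np.vstack([gm.derived_frequency(_resolve(spec, lab)) for lab in labels])
    ok = np.isfinite(freqs).all(axis=0) & gm.polarized_mask
    return freqs, ok


#: minimum jackknife block count; with fewer blocks the variance estimate is
#: unusable, so short inputs fall back to at least this many (or one per site)
MIN_JACKKNIFE_BLOCKS = 20


def block_jackknife_ratio(num: np.ndarray, den: np.ndarray,
                          block_size: int) -> tuple[float, float, int]:
    """Delete-one block jackknife of ``sum(num)/sum(den)`` over consecutive
    equal-size blocks; returns (estimate, SE, n_blocks)."""
    total_n, total_d = num.sum(), den.sum()
    if total_d == 0:
        return float("nan"), float("nan"), 0
    est = total_n / total_d
    g = max(len(num) // block_size, min(MIN_JACKKNIFE_BLOCKS, len(num)))
    edges = np.linspace(0, len(num), g + 1, dtype=int)
    loo = []
    for k in range(g):
        sl = slice(edges[k], edges[k + 1])
        d = total_d - den[sl].sum()
        if d == 0:
            continue
        loo.append((total_n - num[sl].sum()) / d)
    loo = np.asarray(loo)
    if len(loo) < 2:
        return float(est), float("nan"), len(loo)
    se = float(np.sqrt((len(loo) - 1) / len(loo) * ((loo - loo.mean()) ** 2).sum()))
    return float(est), se, len(loo)


@dataclass
class DStatResult:
    """Patterson's D for the quartet (P1, P2; P3, O)."""

    p1: str
    p2: str
    p3: str
    outgroup: str
    abba: float
    baba: float
    d: float
    se: float
    z: float
    n_blocks: int
    n_sites: int

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.z) and abs(self.z) > 3.0)

    def to_row(self) -> dict:
        return {"P1": self.p1, "P2": self.p2, "P3": self.p3, "O": self.outgroup,
                "ABBA": self.abba, "BABA": self.baba, "D": self.d,
                "SE": self.se, "Z": self.z, "n_blocks": self.n_blocks,
                "n_sites": self.n_sites, "significant": self.significant}


def d_statistic(gm: GenotypeMatrix, spec: PopulationSpec, p1: str, p2: str,
                p3: str, outgroup: str,
                block_size: int = DEFAULT_BLOCK_SIZE) -> DStatResult:
    """Patterson's D = sum(ABBA - BABA) / sum(ABBA + BABA) from derived
    frequencies, with SE from a delete-one block jackknife over consecutive
    blocks of polymorphic sites and Z = D/SE.

    Per site, with derived frequencies p1..p4 for (P1, P2, P3, O):
    ``ABBA = (1-p1) p2 p3 (1-p4)`` and ``BABA = p1 (1-p2) p3 (1-p4)``.
    D is NaN when sum(ABBA + BABA) = 0.
    """
    f, ok = _derived_freqs(gm, spec, (p1, p2, p3, outgroup))
    q1, q2, q3, q4 = f[:, ok]
    abba = (1 - q1) * q2 * q3 * (1 - q4)
    baba = q1 * (1 - q2) * q3 * (1 - q4)
    poly = (abba + baba) > 0
    d, se, nb = block_jackknife_ratio((abba - baba)[poly], (abba + baba)[poly],
                                      block_size)
    z = d / se if se and np.isfinite(se) and se > 0 else float("nan")
    return DStatResult(p1, p2, p3, outgroup, float(abba.sum()),
                       float(baba.sum()), d, se, z, nb, int(poly.sum()))


def f4(gm: GenotypeMatrix, spec: PopulationSpec, w: str, x: str, y: str,
       z: str) -> float:
    """f4(W,X;Y,Z) = sum over sites of (pW - pX)(pY - pZ)."""
    f, ok = _derived_freqs(gm, spec, (w, x, y, z))
    qw, qx, qy, qz = f[:, ok]
    return float(((qw - qx) * (qy - qz)).sum())


@dataclass
class F4RatioResult:
    """Admixture proportion alpha = f4(A,O;X,C) / f4(A,O;B,C)."""

    a: str
    b: str
    x: str
    c: str
    outgroup: str
    alpha: float
    se: float
    z_numerator: float        # jackknife Z of the numerator f4 (admixture test)
    p_value: float
    n_blocks: int
    n_sites: int

    @property
    def outside_unit(self) -> bool:
        return bool(np.isfinite(self.alpha) and not 0.0 <= self.alpha <= 1.0)

    def to_row(self) -> dict:
        return {"A": self.a, "B": self.b, "X": self.x, "C": self.c,
                "O": self.outgroup, "alpha": self.alpha, "SE": self.se,
                "Z_num": self.z_numerator, "p": self.p_value,
                "n_blocks": self.n_blocks, "n_sites": self.n_sites,
                "outside_unit": self.outside_unit}


def f4_ratio(gm: GenotypeMatrix, spec: PopulationSpec, a: str, b: str, x: str,
             c: str, outgroup: str,
             block_size: int = DEFAULT_BLOCK_SIZE) -> F4RatioResult:
    """f4-ratio estimate of the admixture proportion contributed by the donor
    clade (containing A and B) to the target X, with C the unadmixed
    reference of X's clade and O the outgroup.

    alpha is reported raw (not clamped to [0, 1]); its SE comes from a
    delete-one block jackknife of the ratio.  The admixture test (Z, p) is
    the jackknife Z of the numerator f4(A,O;X,C).  alpha is NaN when the
    denominator f4 is zero.
    """
    f, ok = _derived_freqs(gm, spec, (a, outgroup, x, c, b))
    qa, qo, qx, qc, qb = f[:, ok]
    num = (qa - qo) * (qx - qc)
    den = (qa - qo) * (qb - qc)
    alpha, se, nb = block_jackknife_ratio(num, den, block_size)
    # numerator-f4 jackknife for the admixture significance test
    f4_num, f4_se, _ = block_jackknife_ratio(num, np.ones_like(num), block_size)
    z = f4_num / f4_se if f4_se and np.isfinite(f4_se) and f4_se > 0 else float("nan")
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return F4RatioResult(a, b, x, c, outgroup, alpha, se, z, p, nb, int(ok.sum()))


def read_quartets(path) -> pd.DataFrame:
    """Quartet configuration TSV with columns A, B, X, C, O."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"A", "B", "X", "C", "O"} - set(df.columns)
    if missing:
        raise ValueError(f"quartet file {path} lacks columns {sorted(missing)}")
    return df


def default_quartets(spec: PopulationSpec, focal_samples, donor_populations
                     ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One quartet per (focal sample, donor).

    The donor clade's A and B must use disjoint sample sets — shared sampling
    noise between the numerator's and denominator's f4 otherwise inflates the
    denominator and biases alpha toward zero — so each donor population is
    split into two halves standing in for A and B.  C is the focal
    individual's own population with the focal individual removed.  Returns
    the quartet frame and the auxiliary group -> samples map.
    """
    rows = []
    groups: dict[str, list[str]] = {}
    for x in focal_samples:
        own_pop = spec.mapping[x]
        ref = [s for s in spec.samples_in(own_pop) if s != x]
        if not ref:
            continue
        c_label = f"__C_{own_pop}__{x}"
        groups[c_label] = ref
        for donor in donor_populations:
            ds = spec.samples_in(donor)
            if len(ds) >= 2:
                a_label, b_label = f"__A_{donor}", f"__B_{donor}"
                groups[a_label] = ds[: len(ds) // 2]
                groups[b_label] = ds[len(ds) // 2:]
            else:
                a_label = b_label = donor
            rows.append({"A": a_label, "B": b_label, "X": x, "C": c_label,
                         "O": spec.outgroup, "donor": donor})
    return pd.DataFrame(rows), groups


def per_individual_mean_introgression(gm: GenotypeMatrix, spec: PopulationSpec,
                                      focal_samples, donor_populations,
                                      fdr: float = 0.05,
                                      quartets: pd.DataFrame | None = None,
                                      block_size: int = DEFAULT_BLOCK_SIZE,
                                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """f4-ratio per (focal individual, donor) with BH-FDR across all tests.

    Returns ``(tests, summary)``: ``tests`` has one row per quartet with
    alpha, SE, p, q and a ``retained`` flag (q < fdr); ``summary`` has one
    row per focal sample and donor with the mean retained alpha (0 with
    ``n_retained = 0`` when no test survives) plus the unfiltered mean.
    """
    from statsmodels.stats.multitest import multipletests

    groups: dict[str, list[str]] = {}
    if quartets is None:
        quartets, groups = default_quartets(spec, focal_samples,
                                            donor_populations)
    if "donor" not in quartets.columns:
        quartets = quartets.assign(donor=quartets["A"])
    rows = []
    for q in quartets.itertuples(index=False):
        used = {lab: groups[lab] for lab in (q.A, q.B, q.C) if lab in groups}
        if used:
            mapping = dict(spec.mapping)
            for lab, samples in used.items():
                mapping.update({s: lab for s in samples})
            sub_spec = PopulationSpec(mapping, outgroup=spec.outgroup)
        else:
            sub_spec = spec
        res = f4_ratio(gm, sub_spec, q.A, q.B, q.X, q.C, q.O, block_size)
        row = res.to_row()
        row["donor"] = q.donor
        rows.append(row)
    tests = pd.DataFrame(rows)
    finite = tests["p"].notna()
    tests["q"] = np.nan
    if finite.any():
        tests.loc[finite, "q"] = multipletests(tests.loc[finite, "p"],
                                               method="fdr_bh")[1]
    tests["retained"] = tests["q"] < fdr

    summary_rows = []
    for (x, donor), grp in tests.groupby(["X", "donor"], sort=False):
        kept = grp[grp["retained"]]
        summary_rows.append({
            "X": x, "donor": donor,
            "mean_alpha_retained": float(kept["alpha"].mean()) if len(kept) else 0.0,
            "n_retained": int(len(kept)),
            "mean_alpha_all": float(grp["alpha"].mean()),
            "n_tests": int(len(grp)),
        })
    return tests, pd.DataFrame(summary_rows)
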