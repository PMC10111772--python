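"""Multi-sample SNP data model, VCF I/O, hard site filters, and outgroup polarization.

The central container is :class:`GenotypeMatrix`: an ordered sample list, a site
table (pandas DataFrame, one row per biallelic SNP with its INFO annotations and
ancestral-allele state), and a dense samples x sites dosage matrix (count of the
ALT allele, ``-1`` for missing).  Internally all interval arithmetic is 0-based
half-open; VCF/BED conventions apply only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: site-table columns holding VCF annotations used by the hard filters
INFO_COLUMNS = ("QUAL", "QD", "FS", "MQ", "DP", "MQRankSum", "ReadPosRankSum")

_BASES = frozenset("ACGT")


class VCFParseError(ValueError):
    """Raised when a VCF cannot be parsed."""


class ConfigurationError(ValueError):
    """Raised when inputs are mutually inconsistent (e.g. unknown sample ids)."""


@dataclass(frozen=True)
class PopulationSpec:
    """Sample -> population mapping with designated outgroup sample(s).

    Parameters
    ----------
    mapping
        sample id -> population label for every sample, outgroup included.
    outgroup
        population label whose samples polarize the ancestral allele.
    """

    mapping: dict[str, str]
    outgroup: str | None = None

    def __post_init__(self):
        if self.outgroup is not None and self.outgroup not in self.mapping.values():
            raise ConfigurationError(f"outgroup label {self.outgroup!r} has no samples")

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for pop in self.mapping.values():
            seen.setdefault(pop)
        return list(seen)

    @property
    def ingroup_populations(self) -> list[str]:
        return [p for p in self.populations if p != self.outgroup]

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.mapping.items() if p == population]

    @property
    def outgroup_samples(self) -> list[str]:
        if self.outgroup is None:
            return []
        return self.samples_in(self.outgroup)

    @classmethod
    def from_tsv(cls, path, outgroup: str | None = None) -> "PopulationSpec":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ConfigurationError(f"population map {path} needs 2 columns")
        return cls(dict(zip(df[0], df[1])), outgroup=outgroup)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.mapping.items():
                fh.write(f"{s}\t{p}\n")


@dataclass(frozen=True)
class FilterConfig:
    """Hard-filter thresholds for raw SNP calls.

    Defaults follow GATK-style hard filtering as used for large mammal
    re-sequencing panels: QD < 2.0, FS > 60.0, MQ < 40.0, QUAL < 30,
    DP < 4.0, MQRankSum < -12.5 and ReadPosRankSum < -8.0 fail; summed
    per-site depth must lie within (1/3x, 3x) of the panel mean; sites with
    >= 10% missing genotype calls or within 5 bp of an assembly gap are
    removed; only biallelic SNPs are kept.
    """

    min_qd: float = 2.0
    max_fs: float = 60.0
    min_mq: float = 40.0
    min_qual: float = 30.0
    min_dp: float = 4.0
    min_mq_rank_sum: float = -12.5
    min_read_pos_rank_sum: float = -8.0
    depth_bounds: tuple[float, float] = (1.0 / 3.0, 3.0)
    max_missing: float = 0.10
    gap_distance: int = 5
    biallelic_only: bool = True
    mean_depth: float | None = None  # freeze depth bounds at an externally supplied mean

    def __post_init__(self):
        if not 0.0 <= self.max_missing <= 1.0:
            raise ConfigurationError("max_missing must be in [0, 1]")
        lo, hi = self.depth_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
            raise ConfigurationError("depth_bounds must be finite with 0 < lo < hi")


@dataclass
class FilterReport:
    """Per-rule removal accounting for one :func:`apply_site_filters` run."""

    n_input: int
    n_output: int
    removed_by_rule: dict[str, int]
    skipped_rules: list[str]
    resolved_depth_bounds: tuple[float, float] | None

    def to_frame(self) -> pd.DataFrame:
        rows = [("input_sites", self.n_input), ("output_sites", self.n_output)]
        rows += [(f"removed_{k}", v) for k, v in self.removed_by_rule.items()]
        rows += [(f"skipped_{k}", "yes") for k in self.skipped_rules]
        return pd.DataFrame(rows, columns=["key", "value"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class GenotypeMatrix:
    """Samples x biallelic-SNP dosage matrix with per-site metadata.

    Parameters
    ----------
    samples
        Ordered sample ids.
    sites
        DataFrame with at least ``chrom, pos, ref, alt`` (pos is 1-based);
        optional columns: the :data:`INFO_COLUMNS` and ``ancestral``
        (each of ``"ref"``, ``"alt"``, ``"unknown"``).
    genotypes
        ``(n_samples, n_sites)`` int8 array of ALT-allele dosages in
        {0, 1, 2} with ``-1`` for missing.
    depth
        Optional per-genotype read depth, same shape.
    contig_lengths
        Optional chrom -> length (bp) map, kept for VCF headers and F_ROH
        denominators.
    """

    def __init__(self, samples, sites: pd.DataFrame, genotypes: np.ndarray,
                 depth: np.ndarray | None = None,
                 contig_lengths: dict[str, int] | None = None):
        self.samples = list(samples)
        self.sites = sites.reset_index(drop=True)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        self.depth = None if depth is None else np.asarray(depth)
        self.contig_lengths = dict(contig_lengths or {})
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites")
        if "ancestral" not in self.sites.columns:
            self.sites["ancestral"] = "unknown"
        self._validate_sites()

    # ------------------------------------------------------------------ basics

    def _validate_sites(self) -> None:
        s = self.sites
        if len(s) == 0:
            return
        if (s["pos"] < 1).any():
            raise ValueError("site positions must be >= 1 (1-based)")
        bad = (s["ref"] == s["alt"]) | ~s["ref"].isin(_BASES) | ~s["alt"].isin(_BASES)
        if bad.any():
            raise ValueError(f"{int(bad.sum())} sites with invalid ref/alt alleles")
        key = list(zip(s["chrom"], s["pos"]))
        if any(k2 <= k1 for k1, k2 in zip(key, key[1:])):
            raise ValueError("sites must be sorted by (chrom, pos) without duplicates")
        g = self.genotypes
        if g.size and (((g < 0) & (g != MISSING)) | (g > 2)).any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise ConfigurationError(f"sample {sample!r} not in matrix") from None

    def sample_indices(self, samples) -> np.ndarray:
        return np.array([self.sample_index(s) for s in samples], dtype=int)

    def take_sites(self, index) -> "GenotypeMatrix":
        """Subset (or reorder) sites by boolean mask or integer index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.samples, self.sites.iloc[index],
            self.genotypes[:, index],
            None if self.depth is None else self.depth[:, index],
            self.contig_lengths)

    def take_samples(self, samples) -> "GenotypeMatrix":
        idx = self.sample_indices(samples)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.sites,
            self.genotypes[idx],
            None if self.depth is None else self.depth[idx],
            self.contig_lengths)

    # ------------------------------------------------------ allele bookkeeping

    def allele_counts(self, samples=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (ALT allele count, called allele copies) over ``samples``."""
        g = self.genotypes if samples is None else self.genotypes[self.sample_indices(samples)]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        return alt, 2 * called.sum(axis=0)

    def allele_frequency(self, samples=None) -> np.ndarray:
        alt, n = self.allele_counts(samples)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    @property
    def polarized_mask(self) -> np.ndarray:
        """True for sites whose ancestral allele is known."""
        return (self.sites["ancestral"].to_numpy() != "unknown")

    def derived_dosage(self, samples=None) -> np.ndarray:
        """ALT dosage re-oriented to count the derived (non-ancestral) allele.

        Sites with unknown ancestral state are returned entirely missing.
        """
        g = self.genotypes if samples is None else self.genotypes[self.sample_indices(samples)]
        anc = self.sites["ancestral"].to_numpy()
        d = g.copy()
        flip = anc == "alt"
        sub = d[:, flip]
        d[:, flip] = np.where(sub == MISSING, MISSING, 2 - sub)
        d[:, anc == "unknown"] = MISSING
        return d

    def derived_frequency(self, samples=None) -> np.ndarray:
        d = self.derived_dosage(samples)
        called = d != MISSING
        n = called.sum(axis=0) * 2
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, np.where(called, d, 0).sum(axis=0) / np.maximum(n, 1), np.nan)

    # ------------------------------------------------------------------- VCF IO

    def write_vcf(self, path) -> None:
        """Write a plain-text VCF 4.2 with GT (and DP when depth is present)."""
        s = self.sites
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=founderpop\n")
            for chrom, length in self.contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            for key in ("QD", "FS", "MQ", "DP", "MQRankSum", "ReadPosRankSum"):
                num_type = "Integer" if key == "DP" else "Float"
                fh.write(f'##INFO=<ID={key},Number=1,Type={num_type},Description="{key}">\n')
            fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            if self.depth is not None:
                fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            fmt = "GT" if self.depth is None else "GT:DP"
            for j in range(self.n_sites):
                row = s.iloc[j]
                info = []
                for key in ("QD", "FS", "MQ", "DP", "MQRankSum", "ReadPosRankSum"):
                    if key in s.columns and pd.notna(row[key]):
                        val = int(row[key]) if key == "DP" else f"{row[key]:g}"
                        info.append(f"{key}={val}")
                if row["ancestral"] != "unknown":
                    aa = row["ref"] if row["ancestral"] == "ref" else row["alt"]
                    info.append(f"AA={aa}")
                qual = f"{row['QUAL']:g}" if "QUAL" in s.columns and pd.notna(row["QUAL"]) else "."
                cells = [str(row["chrom"]), str(int(row["pos"])), ".", row["ref"], row["alt"],
                         qual, "PASS", ";".join(info) or ".", fmt]
                for i in range(self.n_samples):
                    cell = gt_str[int(self.genotypes[i, j])]
                    if self.depth is not None:
                        cell += f":{int(self.depth[i, j])}"
                    cells.append(cell)
                fh.write("\t".join(cells) + "\n")


def read_vcf(path, population_spec: PopulationSpec | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF 4.x file into a :class:`GenotypeMatrix`.

    Multiallelic records, indels and MNPs are dropped (and counted on the
    returned matrix as ``dropped_records``); half-calls are treated as missing
    and phasing is discarded.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VCFParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if population_spec is not None:
        missing = [s for s in population_spec.mapping if s not in samples]
        if missing:
            raise VCFParseError(
                f"samples in population map absent from VCF {path}: {missing}")
    contigs = {}
    try:
        contigs = dict(zip(vcf.seqnames, vcf.seqlens))
    except Exception:
        pass

    rows, dosage_cols, depth_cols = [], [], []
    dropped = 0
    has_depth = "DP" in {f["ID"] for f in _format_headers(vcf)}
    for lineno, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1 or not var.is_snp or var.ALT[0] not in _BASES \
                or var.REF not in _BASES or len(var.REF) != 1:
            dropped += 1
            continue
        geno = np.full(len(samples), MISSING, dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1] if len(g) > 2 else -1
            if a < 0 or b < 0:  # missing or half-call
                continue
            geno[i] = a + b
        info = {k: _info_float(var, k) for k in ("QD", "FS", "MQ", "DP",
                                                 "MQRankSum", "ReadPosRankSum")}
        aa = var.INFO.get("AA")
        ancestral = "unknown"
        if aa == var.REF:
            ancestral = "ref"
        elif aa == var.ALT[0]:
            ancestral = "alt"
        rows.append({"chrom": var.CHROM, "pos": var.POS, "ref": var.REF,
                     "alt": var.ALT[0], "QUAL": var.QUAL, **info,
                     "ancestral": ancestral})
        dosage_cols.append(geno)
        if has_depth:
            dp = var.format("DP")
            depth_cols.append(np.full(len(samples), -1) if dp is None
                              else np.where(dp[:, 0] < 0, -1, dp[:, 0]))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", *INFO_COLUMNS,
                                        "ancestral"])
    geno = (np.stack(dosage_cols, axis=1) if dosage_cols
            else np.zeros((len(samples), 0), dtype=np.int8))
    depth = np.stack(depth_cols, axis=1) if depth_cols and has_depth else None
    gm = GenotypeMatrix(samples, sites, geno, depth, contigs)
    gm.dropped_records = dropped
    return gm


def _format_headers(vcf):
    try:
        return [h.info() for h in vcf.header_iter() if h.type == "FORMAT"]
    except Exception:
        return []


def _info_float(var, key):
    val = var.INFO.get(key)
    try:
        return float(val) if val is not None else np.nan
    except (TypeError, ValueError):
        return np.nan


# ---------------------------------------------------------------- gap intervals

def read_bed(path) -> dict[str, np.ndarray]:
    """Read BED intervals (0-based half-open) into chrom -> (N, 2) arrays."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return {c: g[["start", "end"]].to_numpy(dtype=np.int64)
            for c, g in df.groupby("chrom", sort=False)}


def gaps_from_fasta(path) -> dict[str, np.ndarray]:
    """Derive assembly-gap intervals (runs of N) from a reference FASTA."""
    from pyfaidx import Fasta

    gaps: dict[str, np.ndarray] = {}
    for name, rec in Fasta(str(path), rebuild=False).items():
        seq = np.frombuffer(str(rec[:]).upper().encode(), dtype="S1")
        is_n = seq == b"N"
        if not is_n.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([False], is_n, [False]))))
        gaps[name] = edges.reshape(-1, 2)
    return gaps


def _near_gap(positions: np.ndarray, intervals: np.ndarray, dist: int) -> np.ndarray:
    """True where a 0-based position is within ``dist`` bp of any interval."""
    if len(intervals) == 0:
        return np.zeros(len(positions), dtype=bool)
    starts = np.maximum(intervals[:, 0] - dist, 0)
    ends = intervals[:, 1] + dist
    order = np.argsort(starts)
    starts, ends = starts[order], np.maximum.accumulate(ends[order])
    idx = np.searchsorted(starts, positions, side="right") - 1
    hit = idx >= 0
    hit[hit] = positions[hit] < ends[idx[hit]]
    return hit


# -------------------------------------------------------------------- filtering

def apply_site_filters(gm: GenotypeMatrix, cfg: FilterConfig,
                       gap_intervals: dict[str, np.ndarray] | None = None,
                       ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply hard site filters and return the surviving matrix plus a report.

    Filters whose INFO annotation is absent from the site table are skipped
    (and listed in the report) rather than failing the run.  Overall-depth
    bounds are multiples of the mean per-site summed DP across all samples,
    unless ``cfg.mean_depth`` pins the mean explicitly.
    """
    s = gm.sites
    n = gm.n_sites
    keep = np.ones(n, dtype=bool)
    removed: dict[str, int] = {}
    skipped: list[str] = []

    def info_rule(name, column, fail_fn):
        if column not in s.columns or s[column].isna().all():
            skipped.append(name)
            logger.warning("filter %s skipped: %s annotation absent", name, column)
            return
        vals = s[column].to_numpy(dtype=float)
        fails = np.where(np.isnan(vals), False, fail_fn(vals))
        removed[name] = int(fails.sum())
        np.logical_and(keep, ~fails, out=keep)

    info_rule("QD", "QD", lambda v: v < cfg.min_qd)
    info_rule("FS", "FS", lambda v: v > cfg.max_fs)
    info_rule("MQ", "MQ", lambda v: v < cfg.min_mq)
    info_rule("QUAL", "QUAL", lambda v: v < cfg.min_qual)
    info_rule("DP", "DP", lambda v: v < cfg.min_dp)
    info_rule("MQRankSum", "MQRankSum", lambda v: v < cfg.min_mq_rank_sum)
    info_rule("ReadPosRankSum", "ReadPosRankSum", lambda v: v < cfg.min_read_pos_rank_sum)

    bounds = None
    if "DP" in s.columns and not s["DP"].isna().all():
        dp = s["DP"].to_numpy(dtype=float)
        mean = cfg.mean_depth if cfg.mean_depth is not None else np.nanmean(dp)
        bounds = (cfg.depth_bounds[0] * mean, cfg.depth_bounds[1] * mean)
        fails = np.where(np.isnan(dp), False, (dp <= bounds[0]) | (dp >= bounds[1]))
        removed["depth_bounds"] = int(fails.sum())
        np.logical_and(keep, ~fails, out=keep)
    else:
        skipped.append("depth_bounds")

    if gm.n_samples > 0 and n > 0:
        miss = (gm.genotypes == MISSING).mean(axis=0)
        fails = miss >= cfg.max_missing
        removed["missing_fraction"] = int(fails.sum())
        np.logical_and(keep, ~fails, out=keep)

    if gap_intervals is not None:
        fails = np.zeros(n, dtype=bool)
        pos0 = s["pos"].to_numpy() - 1
        chroms = s["chrom"].to_numpy()
        for chrom in pd.unique(chroms):
            mask = chroms == chrom
            fails[mask] = _near_gap(pos0[mask], gap_intervals.get(chrom, np.empty((0, 2), int)),
                                    cfg.gap_distance)
        removed["gap_proximity"] = int(fails.sum())
        np.logical_and(keep, ~fails, out=keep)
    else:
        skipped.append("gap_proximity")
        logger.warning("no gap intervals supplied; 5 bp gap filter skipped")

    out = gm.take_sites(keep)
    if out.n_sites == 0:
        logger.warning("all %d sites removed by filtering", n)
    return out, FilterReport(n, out.n_sites, removed, skipped, bounds)


# ----------------------------------------------------------------- polarization

def polarize_by_outgroup(gm: GenotypeMatrix, outgroup: str) -> GenotypeMatrix:
    """Set each site's ancestral allele to the outgroup sample's homozygous allele.

    Sites where the outgroup is heterozygous or missing are marked unknown.
    Returns a new matrix; dosages are unchanged (use
    :meth:`GenotypeMatrix.derived_dosage` for derived-allele orientation).
    """
    og = gm.genotypes[gm.sample_index(outgroup)]
    ancestral = np.where(og == 0, "ref", np.where(og == 2, "alt", "unknown"))
    sites = gm.sites.copy()
    sites["ancestral"] = ancestral
    return GenotypeMatrix(gm.samples, sites, gm.genotypes, gm.depth, gm.contig_lengths)
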