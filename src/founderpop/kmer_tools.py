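"""K-mer depth histograms at toy scale and genome-size estimation.

Genome size is estimated from sequencing reads as
``total k-mer count / peak k-mer depth``: each genomic position contributes
about coverage-many k-mer occurrences, so the modal depth of the k-mer
spectrum estimates the coverage and the quotient the genome length.
K-mers are counted canonically (a k-mer and its reverse complement are the
same key); the depth-1 class, dominated by sequencing-error k-mers on real
data, is excluded from peak finding by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class KmerHistogram:
    k: int
    depth_counts: dict[int, int]     # depth -> number of distinct k-mers at that depth
    total_kmers: int                 # total k-mer occurrences counted
    n_short_reads_skipped: int

    def peak_depth(self, exclude_depth_one: bool = True) -> int:
        """Modal depth of the spectrum (depth 1 excluded by default)."""
        items = [(d, c) for d, c in self.depth_counts.items()
                 if not (exclude_depth_one and d == 1)]
        if not items:
            raise ValueError("empty k-mer spectrum")
        return max(items, key=lambda dc: (dc[1], -dc[0]))[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.depth_counts.items()),
                            columns=["depth", "n_kmers"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


def _canonical_codes(seq: str, k: int) -> np.ndarray:
    """2-bit-packed canonical k-mer codes for one read (int64; k <= 31)."""
    bits = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    valid = bits >= 0
    b = np.where(valid, bits, 0).astype(np.int64)
    win = np.lib.stride_tricks.sliding_window_view(b, k)
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    fwd_p = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    rev_p = 4 ** np.arange(k, dtype=np.int64)
    fwd = win @ fwd_p
    rev = np.lib.stride_tricks.sliding_window_view(3 - b, k) @ rev_p
    return np.minimum(fwd, rev)[ok]


def kmer_histogram(reads_path, k: int = 17) -> KmerHistogram:
    """Exact canonical k-mer counting over a FASTA/FASTQ file.

    K-mers are 2-bit packed and counted exactly (suitable for toy inputs up
    to ~1e8 bases).  Reads shorter than ``k`` and k-mers containing non-ACGT
    characters are skipped.
    """
    from Bio import SeqIO

    if k % 2 == 0 or k < 1 or k > 31:
        raise ValueError("k must be odd, positive, and at most 31")
    fmt = "fastq" if str(reads_path).endswith(("fastq", "fq")) else "fasta"
    chunks = []
    skipped = 0
    for rec in SeqIO.parse(str(reads_path), fmt):
        seq = str(rec.seq)
        if len(seq) < k:
            skipped += 1
            continue
        chunks.append(_canonical_codes(seq, k))
    if chunks:
        codes = np.concatenate(chunks)
        _, per_kmer = np.unique(codes, return_counts=True)
        depths, n_at_depth = np.unique(per_kmer, return_counts=True)
        depth_counts = dict(zip(depths.tolist(), n_at_depth.tolist()))
        total = int(codes.size)
    else:
        depth_counts, total = {}, 0
    return KmerHistogram(k, depth_counts, total, skipped)


def estimate_genome_size(total_kmers: int, peak_depth: int) -> float:
    """Genome size in bp: total k-mer occurrences divided by the peak depth."""
    if peak_depth <= 0:
        raise ValueError("peak depth must be positive")
    return total_kmers / peak_depth


def genome_size_report(hist: KmerHistogram) -> dict:
    peak = hist.peak_depth()
    size = estimate_genome_size(hist.total_kmers, peak)
    return {"k": hist.k, "total_kmers": hist.total_kmers, "peak_depth": peak,
            "genome_size_bp": size, "genome_size_mb": round(size / 1e6, 2),
            "canonical": True, "depth_one_excluded_from_peak": True}
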