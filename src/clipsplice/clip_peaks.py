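"""CLIP peak handling: IO, thresholding, sharing, region annotation, k-mers.

Peaks arrive as BED6+2: the two extra columns carry the log2 fold
enrichment of IP over size-matched input and the -log10 P value from the
peak caller's per-region Fisher test.  Enrichment thresholds are strict:
a peak is significant when log2(FC) and -log10(P) both *exceed* their
cutoffs (5/5 for TDP-43, 3/3 for NOVA1, NOVA2 and RBFOX2).

All interval arithmetic is 0-based half-open and strand-aware: two
features overlap only when they share >= 1 base on the same strand.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakThreshold",
    "GeneInterval",
    "KmerResult",
    "NOVA_THRESHOLD",
    "TDP43_THRESHOLD",
    "read_peaks",
    "write_peaks",
    "threshold_peaks",
    "peak_share_fraction",
    "transcript_share_fraction",
    "annotate_regions",
    "kmer_enrichment",
    "count_kmers",
    "DEFAULT_REGION_PRIORITY",
]


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    strand: str
    rbp: str
    log2_fc: float
    neg_log10_p: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: negative start")
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: bad strand {self.strand!r}")
        if self.neg_log10_p < 0:
            raise ValueError("neg_log10_p must be >= 0")


@dataclass(frozen=True)
class PeakThreshold:
    min_log2_fc: float
    min_neg_log10_p: float


# thresholds used to call significantly enriched peaks per RBP
NOVA_THRESHOLD = PeakThreshold(3.0, 3.0)
TDP43_THRESHOLD = PeakThreshold(5.0, 5.0)


@dataclass(frozen=True)
class GeneInterval:
    """One labeled interval of a simplified gene model (BED6, label in name)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene: str
    region_class: str


@dataclass(frozen=True)
class KmerResult:
    kmer: str
    freq_fg: float
    freq_bg: float
    z: float


def read_peaks(path: str | Path) -> list[Peak]:
    """Read BED6+2 (chrom, start, end, name=rbp, score, strand, log2FC, -log10P)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}: line {line_no}: expected 8 BED columns, got {len(parts)}")
            try:
                peaks.append(
                    Peak(
                        chrom=parts[0],
                        start=int(parts[1]),
                        end=int(parts[2]),
                        rbp=parts[3],
                        strand=parts[5],
                        log2_fc=float(parts[6]),
                        neg_log10_p=float(parts[7]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_no}: {exc}") from exc
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.rbp}\t0\t{p.strand}"
                f"\t{p.log2_fc!r}\t{p.neg_log10_p!r}\n"
            )


def threshold_peaks(peaks: Sequence[Peak], th: PeakThreshold) -> list[Peak]:
    """Keep peaks strictly exceeding both enrichment cutoffs."""
    return [
        p for p in peaks if p.log2_fc > th.min_log2_fc and p.neg_log10_p > th.min_neg_log10_p
    ]


class _IntervalLookup:
    """Sorted per-(chrom, strand) interval index for >=1 bp overlap queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]]):
        by_key: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
        for chrom, start, end, strand in intervals:
            by_key[(chrom, strand)].append((start, end))
        self._starts: dict[tuple[str, str], list[int]] = {}
        self._maxend: dict[tuple[str, str], list[int]] = {}
        self._ivs: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for key, ivs in by_key.items():
            ivs.sort()
            self._ivs[key] = ivs
            self._starts[key] = [s for s, _ in ivs]
            running = []
            m = -1
            for _, e in ivs:
                m = max(m, e)
                running.append(m)
            self._maxend[key] = running

    def overlaps(self, chrom: str, start: int, end: int, strand: str) -> bool:
        key = (chrom, strand)
        if key not in self._ivs:
            return False
        starts = self._starts[key]
        hi = bisect_right(starts, end - 1)  # intervals starting before `end`
        if hi == 0:
            return False
        # any of those intervals ending after `start` overlaps
        return self._maxend[key][hi - 1] > start


def peak_share_fraction(a: Sequence[Peak], b: Sequence[Peak]) -> float:
    """Fraction of peaks in `a` overlapping >=1 bp with a same-strand peak in `b`."""
    if len(a) == 0:
        raise ValueError("peak sharing undefined for an empty query set")
    lookup = _IntervalLookup((p.chrom, p.start, p.end, p.strand) for p in b)
    hit = sum(lookup.overlaps(p.chrom, p.start, p.end, p.strand) for p in a)
    return hit / len(a)


def _genes_hit(peaks: Sequence[Peak], gene_model: Sequence[GeneInterval]) -> set[str]:
    spans: dict[str, list] = defaultdict(lambda: [None, math.inf, -math.inf, None])
    for gi in gene_model:
        rec = spans[gi.gene]
        rec[0] = gi.chrom
        rec[1] = min(rec[1], gi.start)
        rec[2] = max(rec[2], gi.end)
        rec[3] = gi.strand
    hit: set[str] = set()
    for gene, (chrom, start, end, strand) in spans.items():
        lookup_key = (chrom, strand)
        for p in peaks:
            if (p.chrom, p.strand) == lookup_key and p.start < end and p.end > start:
                hit.add(gene)
                break
    return hit


def transcript_share_fraction(
    a: Sequence[Peak], b: Sequence[Peak], gene_model: Sequence[GeneInterval]
) -> float:
    """Fraction of genes bound by `a` that are also bound by `b`.

    A gene counts as bound when >= 1 peak overlaps its span on the same
    strand.
    """
    if not gene_model:
        raise ValueError("empty gene model")
    genes_a = _genes_hit(a, gene_model)
    if not genes_a:
        raise ValueError("no genes hit by the query peak set")
    genes_b = _genes_hit(b, gene_model)
    return len(genes_a & genes_b) / len(genes_a)


DEFAULT_REGION_PRIORITY = ("CDS", "3UTR", "5UTR", "noncoding_exon", "intron")


def annotate_regions(
    peaks: Sequence[Peak],
    gene_model: Sequence[GeneInterval],
    priority: Sequence[str] = DEFAULT_REGION_PRIORITY,
) -> pd.DataFrame:
    """Assign each peak one region class by fixed priority.

    Among overlapping gene-model intervals the class earliest in
    ``priority`` wins; ties within a class go to the longest overlap.
    Peaks overlapping nothing are ``intergenic``.  Returns a DataFrame
    with ``count`` and ``fraction`` per class (fractions sum to 1).
    """
    rank = {cls: i for i, cls in enumerate(priority)}
    counts: dict[str, int] = defaultdict(int)
    by_key: dict[tuple[str, str], list[GeneInterval]] = defaultdict(list)
    for gi in gene_model:
        by_key[(gi.chrom, gi.strand)].append(gi)
    for p in peaks:
        best: tuple[int, int] | None = None  # (priority rank, -overlap)
        best_cls = "intergenic"
        for gi in by_key.get((p.chrom, p.strand), ()):
            ov = min(p.end, gi.end) - max(p.start, gi.start)
            if ov <= 0:
                continue
            r = rank.get(gi.region_class, len(priority))
            cand = (r, -ov)
            if best is None or cand < best:
                best = cand
                best_cls = gi.region_class
        counts[best_cls] += 1
    total = max(1, len(peaks))
    classes = sorted(counts)
    return pd.DataFrame(
        {
            "region_class": classes,
            "count": [counts[c] for c in classes],
            "fraction": [counts[c] / total for c in classes],
        }
    )


def count_kmers(seqs: Iterable[str], k: int) -> tuple[dict[str, int], int]:
    """Sliding-window k-mer counts over upper-cased sequences; windows with N skipped.

    U is treated as T.  Returns (counts, total positions counted).
    """
    counts: dict[str, int] = defaultdict(int)
    total = 0
    valid = set("ACGT")
    for seq in seqs:
        s = seq.upper().replace("U", "T")
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= valid:
                counts[w] += 1
                total += 1
    return dict(counts), total


def kmer_enrichment(
    fg_seqs: Sequence[str], bg_seqs: Sequence[str], k: int = 4
) -> list[KmerResult]:
    """Z-test of foreground k-mer frequencies against an empirical background.

    z(w) = (f_fg - f_bg) / sqrt(f_bg (1 - f_bg) / N_fg), the one-sample
    binomial approximation with the background frequency as the null rate.
    k-mers absent from the background get a pseudo-frequency of
    1/(N_bg + 4^k).  Results are sorted by descending z.
    """
    fg_counts, n_fg = count_kmers(fg_seqs, k)
    bg_counts, n_bg = count_kmers(bg_seqs, k)
    if n_fg == 0 or n_bg == 0:
        raise ValueError("foreground and background must each contain >= 1 valid k-mer window")
    pseudo = 1.0 / (n_bg + 4**k)
    results = []
    for w in sorted(set(fg_counts) | set(bg_counts)):
        f_fg = fg_counts.get(w, 0) / n_fg
        f_bg = bg_counts.get(w, 0) / n_bg
        if f_bg == 0.0:
            f_bg = pseudo
        z = (f_fg - f_bg) / math.sqrt(f_bg * (1 - f_bg) / n_fg)
        results.append(KmerResult(w, f_fg, f_bg, z))
    results.sort(key=lambda r: (-r.z, r.kmer))
    return results
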