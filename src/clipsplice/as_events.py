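"""Cassette-exon (skipped exon) event handling for rMATS-style tables.

Consumes the junction-count (JC) dialect of rMATS 4.1.0 ``SE.MATS.JC.txt``:
one row per cassette exon with per-replicate inclusion/skipping junction
counts for two groups, an inclusion-level difference (dPSI), and an FDR.
Coordinates are 0-based half-open, matching rMATS ``exonStart_0base`` and
BED.

Sign convention (fixed by how the two groups are assigned): group 1 is the
control condition and group 2 the target condition, so a *negative* dPSI
means the exon is *included* in the target condition and a positive dPSI
means it is *excluded* there.

``upstreamES/EE`` columns are interpreted as the genomically-left flanking
exon regardless of strand; transcript orientation is restored downstream
(see :mod:`clipsplice.splice_enrichment`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, fisher_exact_2x2, spearman

logger = logging.getLogger(__name__)

__all__ = [
    "ASEvent",
    "SignConvention",
    "OverlapResult",
    "read_rmats",
    "write_events_tsv",
    "coverage_filter",
    "call_significant",
    "event_key",
    "index_events",
    "join_datasets",
    "overlap_test",
    "dpsi_correlation",
    "RMATS_COLUMNS",
]

RMATS_COLUMNS = [
    "ID",
    "GeneID",
    "geneSymbol",
    "chr",
    "strand",
    "exonStart_0base",
    "exonEnd",
    "upstreamES",
    "upstreamEE",
    "downstreamES",
    "downstreamEE",
    "IJC_SAMPLE_1",
    "SJC_SAMPLE_1",
    "IJC_SAMPLE_2",
    "SJC_SAMPLE_2",
    "IncFormLen",
    "SkipFormLen",
    "PValue",
    "FDR",
    "IncLevel1",
    "IncLevel2",
    "IncLevelDifference",
]


@dataclass(frozen=True)
class ASEvent:
    """One cassette-exon event with per-replicate junction support."""

    event_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    alt_exon_start: int
    alt_exon_end: int
    left_flank_start: int
    left_flank_end: int
    right_flank_start: int
    right_flank_end: int
    ijc_g1: tuple[int, ...]
    sjc_g1: tuple[int, ...]
    ijc_g2: tuple[int, ...]
    sjc_g2: tuple[int, ...]
    inc_form_len: int
    skip_form_len: int
    p_value: float
    fdr: float
    inc_level_g1: tuple[float | None, ...] = field(default=())
    inc_level_g2: tuple[float | None, ...] = field(default=())
    inc_level_difference: float = float("nan")

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"event {self.event_id}: invalid strand {self.strand!r}")
        if not (
            self.left_flank_end <= self.alt_exon_start < self.alt_exon_end <= self.right_flank_start
        ):
            raise ValueError(
                f"event {self.event_id}: exon ordering violated "
                f"(flankL end {self.left_flank_end}, alt [{self.alt_exon_start},"
                f"{self.alt_exon_end}), flankR start {self.right_flank_start})"
            )
        if len(self.ijc_g1) != len(self.sjc_g1) or len(self.ijc_g2) != len(self.sjc_g2):
            raise ValueError(f"event {self.event_id}: count list lengths differ within a group")
        if np.isfinite(self.inc_level_difference) and abs(self.inc_level_difference) > 1 + 1e-9:
            raise ValueError(f"event {self.event_id}: |dPSI| > 1")

    @property
    def sample_totals(self) -> tuple[int, ...]:
        """Per-replicate IJC + SJC across both groups, in table order."""
        g1 = tuple(i + s for i, s in zip(self.ijc_g1, self.sjc_g1))
        g2 = tuple(i + s for i, s in zip(self.ijc_g2, self.sjc_g2))
        return g1 + g2

    @property
    def total_support(self) -> int:
        return sum(self.sample_totals)


@dataclass(frozen=True)
class SignConvention:
    """Which condition each rMATS group carries and the dPSI direction rule.

    Negative dPSI = exon included in the target condition (group 2);
    positive dPSI = exon excluded there.
    """

    group1_label: str = "control"
    group2_label: str = "target"

    def direction(self, dpsi: float) -> str:
        if dpsi < 0:
            return "included"
        if dpsi > 0:
            return "excluded"
        raise ValueError("direction undefined for dPSI == 0")


@dataclass(frozen=True)
class OverlapResult:
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    odds_ratio: float
    p_fisher: float
    or_infinite: bool = False


def _parse_int_list(text: str, line_no: int, col: str) -> tuple[int, ...]:
    try:
        vals = tuple(int(v) for v in str(text).split(","))
    except ValueError as exc:
        raise ValueError(f"line {line_no}: non-numeric count in {col}: {text!r}") from exc
    if any(v < 0 for v in vals):
        raise ValueError(f"line {line_no}: negative count in {col}: {text!r}")
    return vals


def _parse_psi_list(text: str) -> tuple[float | None, ...]:
    out: list[float | None] = []
    for v in str(text).split(","):
        v = v.strip()
        out.append(None if v in ("NA", "nan", "") else float(v))
    return tuple(out)


def read_rmats(path: str | Path) -> list[ASEvent]:
    """Parse an rMATS-dialect SE junction-count table into events.

    Raises a format error naming the first missing mandatory column;
    malformed rows raise with their 1-based line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in RMATS_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    events: list[ASEvent] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # header is line 1
        r = dict(zip(df.columns, row))
        try:
            ev = ASEvent(
                event_id=str(r["ID"]),
                gene_id=str(r["GeneID"]),
                gene_symbol=str(r["geneSymbol"]),
                chrom=str(r["chr"]),
                strand=str(r["strand"]),
                alt_exon_start=int(r["exonStart_0base"]),
                alt_exon_end=int(r["exonEnd"]),
                left_flank_start=int(r["upstreamES"]),
                left_flank_end=int(r["upstreamEE"]),
                right_flank_start=int(r["downstreamES"]),
                right_flank_end=int(r["downstreamEE"]),
                ijc_g1=_parse_int_list(r["IJC_SAMPLE_1"], line_no, "IJC_SAMPLE_1"),
                sjc_g1=_parse_int_list(r["SJC_SAMPLE_1"], line_no, "SJC_SAMPLE_1"),
                ijc_g2=_parse_int_list(r["IJC_SAMPLE_2"], line_no, "IJC_SAMPLE_2"),
                sjc_g2=_parse_int_list(r["SJC_SAMPLE_2"], line_no, "SJC_SAMPLE_2"),
                inc_form_len=int(r["IncFormLen"]),
                skip_form_len=int(r["SkipFormLen"]),
                p_value=float(r["PValue"]),
                fdr=float(r["FDR"]),
                inc_level_g1=_parse_psi_list(r["IncLevel1"]),
                inc_level_g2=_parse_psi_list(r["IncLevel2"]),
                inc_level_difference=float(r["IncLevelDifference"]),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc
        events.append(ev)
    return events


def write_events_tsv(events: Iterable[ASEvent], path: str | Path) -> None:
    """Write events back in the rMATS dialect, with an added event_key column."""
    rows = []
    for ev in events:
        rows.append(
            {
                "ID": ev.event_id,
                "GeneID": ev.gene_id,
                "geneSymbol": ev.gene_symbol,
                "chr": ev.chrom,
                "strand": ev.strand,
                "exonStart_0base": ev.alt_exon_start,
                "exonEnd": ev.alt_exon_end,
                "upstreamES": ev.left_flank_start,
                "upstreamEE": ev.left_flank_end,
                "downstreamES": ev.right_flank_start,
                "downstreamEE": ev.right_flank_end,
                "IJC_SAMPLE_1": ",".join(map(str, ev.ijc_g1)),
                "SJC_SAMPLE_1": ",".join(map(str, ev.sjc_g1)),
                "IJC_SAMPLE_2": ",".join(map(str, ev.ijc_g2)),
                "SJC_SAMPLE_2": ",".join(map(str, ev.sjc_g2)),
                "IncFormLen": ev.inc_form_len,
                "SkipFormLen": ev.skip_form_len,
                "PValue": repr(ev.p_value),
                "FDR": repr(ev.fdr),
                "IncLevel1": ",".join("NA" if v is None else repr(v) for v in ev.inc_level_g1),
                "IncLevel2": ",".join("NA" if v is None else repr(v) for v in ev.inc_level_g2),
                "IncLevelDifference": repr(ev.inc_level_difference),
                "event_key": event_key(ev),
            }
        )
    pd.DataFrame(rows, columns=RMATS_COLUMNS + ["event_key"]).to_csv(path, sep="\t", index=False)


def coverage_filter(events: Sequence[ASEvent], min_reads: int = 10) -> list[ASEvent]:
    """Keep events whose IJC+SJC total is >= min_reads in *every* replicate."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    return [ev for ev in events if all(t >= min_reads for t in ev.sample_totals)]


def call_significant(
    events: Sequence[ASEvent], fdr_max: float = 0.05, min_abs_dpsi: float = 0.1
) -> list[ASEvent]:
    """Significant events: FDR strictly below fdr_max and |dPSI| strictly above min_abs_dpsi."""
    return [
        ev
        for ev in events
        if ev.fdr < fdr_max and abs(ev.inc_level_difference) > min_abs_dpsi
    ]


def event_key(event: ASEvent) -> str:
    """Canonical key identifying the splice junctions of a cassette event.

    Only the four junction-defining coordinates enter the key (flank inner
    boundaries and the alternative exon), so the same junction annotated
    with different flank outer boundaries in two rMATS runs still matches.
    """
    return (
        f"{event.chrom}:{event.strand}:{event.left_flank_end}:"
        f"{event.alt_exon_start}:{event.alt_exon_end}:{event.right_flank_start}"
    )


def index_events(events: Sequence[ASEvent]) -> dict[str, ASEvent]:
    """Map event_key -> event, resolving duplicates to the best-supported row.

    Duplicate keys keep the row with the larger total junction count
    (deterministic; earlier row wins ties) and log a warning.
    """
    out: dict[str, ASEvent] = {}
    n_dup = 0
    for ev in events:
        key = event_key(ev)
        prev = out.get(key)
        if prev is None:
            out[key] = ev
        else:
            n_dup += 1
            if ev.total_support > prev.total_support:
                out[key] = ev
    if n_dup:
        logger.warning("index_events: resolved %d duplicate event keys", n_dup)
    return out


def join_datasets(a: Sequence[ASEvent], b: Sequence[ASEvent]) -> pd.DataFrame:
    """Inner join of two coverage-filtered event sets on the canonical key.

    Returns a DataFrame indexed by event_key with dpsi/fdr columns from
    both datasets (suffixes ``_a`` and ``_b``) plus the event objects.
    """
    ia, ib = index_events(a), index_events(b)
    keys = [k for k in ia if k in ib]
    return pd.DataFrame(
        {
            "dpsi_a": [ia[k].inc_level_difference for k in keys],
            "fdr_a": [ia[k].fdr for k in keys],
            "dpsi_b": [ib[k].inc_level_difference for k in keys],
            "fdr_b": [ib[k].fdr for k in keys],
            "event_a": [ia[k] for k in keys],
            "event_b": [ib[k] for k in keys],
        },
        index=pd.Index(keys, name="event_key"),
    )


def overlap_test(
    joined: pd.DataFrame,
    sig_flags_a: Sequence[bool],
    sig_flags_b: Sequence[bool],
) -> OverlapResult:
    """Fisher's exact test for the overlap of significant calls on a shared background.

    The background is the joined table (events passing coverage in both
    datasets); the 2x2 table cross-classifies significance in A and B.
    """
    fa = np.asarray(sig_flags_a, dtype=bool)
    fb = np.asarray(sig_flags_b, dtype=bool)
    if len(fa) != len(joined) or len(fb) != len(joined):
        raise ValueError("flag vectors must match the joined table length")
    n_both = int((fa & fb).sum())
    n_a_only = int((fa & ~fb).sum())
    n_b_only = int((~fa & fb).sum())
    n_neither = int((~fa & ~fb).sum())
    res = fisher_exact_2x2([[n_both, n_a_only], [n_b_only, n_neither]])
    return OverlapResult(
        n_both,
        n_a_only,
        n_b_only,
        n_neither,
        odds_ratio=res.statistic,
        p_fisher=res.p_two_sided,
        or_infinite=res.extra.get("or_infinite", False),
    )


def dpsi_correlation(joined: pd.DataFrame) -> TestResult:
    """Spearman correlation of the two dPSI columns of a joined table."""
    if len(joined) < 3:
        raise ValueError("dPSI correlation needs >= 3 joined events")
    return spearman(joined["dpsi_a"].to_numpy(), joined["dpsi_b"].to_numpy())
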