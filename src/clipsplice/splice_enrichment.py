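"""Positional enrichment of CLIP peaks at cassette-exon events.

A cassette event decomposes into five transcript-oriented sub-regions --
upstream exon, upstream intron, alternative exon, downstream intron,
downstream exon -- plus the full junction span. rMATS reports the
genomically-left flank as "upstream" regardless of strand, so on the
minus strand the genomic-left flank is actually the *downstream* exon in
transcript orientation; the label swap below restores transcript
orientation while leaving genomic coordinates untouched.

Enrichment of peaks at a selected event set against a coverage-passed
background uses the hypergeometric upper tail: with N background events,
K of which carry >= 1 same-strand peak in the region, and n selected
events of which k carry one, P = P(X >= k) for X ~ HG(N, K, n).  Events
count once no matter how many peaks they contain (bedtools ``-u``
semantics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .as_events import ASEvent, SignConvention
from .clip_peaks import Peak, _IntervalLookup
from .stats import hypergeom_sf

__all__ = [
    "RegionSpan",
    "EnrichmentResult",
    "REGION_LABELS",
    "event_regions",
    "events_with_peak",
    "region_enrichment",
    "positional_profile",
    "proximal_window_enrichment",
    "profile_to_frame",
]

REGION_LABELS = (
    "upstream_exon",
    "upstream_intron",
    "alternative_exon",
    "downstream_intron",
    "downstream_exon",
    "junction_span",
)


@dataclass(frozen=True)
class RegionSpan:
    label: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class EnrichmentResult:
    region: str
    direction: str  # all | included | excluded
    n_background: int
    k_background: int
    n_selected: int
    k_selected: int
    fold_enrichment: float  # nan when k_background == 0
    p_hypergeom: float
    fold_defined: bool = True


def event_regions(event: ASEvent) -> list[RegionSpan]:
    """Decompose one event into transcript-oriented spans.

    Zero-length introns (abutting exons) are dropped rather than emitted
    as empty intervals.
    """
    e = event
    genomic = {
        "left_exon": (e.left_flank_start, e.left_flank_end),
        "left_intron": (e.left_flank_end, e.alt_exon_start),
        "alternative_exon": (e.alt_exon_start, e.alt_exon_end),
        "right_intron": (e.alt_exon_end, e.right_flank_start),
        "right_exon": (e.right_flank_start, e.right_flank_end),
        "junction_span": (e.left_flank_start, e.right_flank_end),
    }
    if e.strand == "+":
        label_map = {
            "left_exon": "upstream_exon",
            "left_intron": "upstream_intron",
            "right_intron": "downstream_intron",
            "right_exon": "downstream_exon",
        }
    else:
        # minus strand: genomic left is transcript-downstream
        label_map = {
            "left_exon": "downstream_exon",
            "left_intron": "downstream_intron",
            "right_intron": "upstream_intron",
            "right_exon": "upstream_exon",
        }
    label_map["alternative_exon"] = "alternative_exon"
    label_map["junction_span"] = "junction_span"
    spans = []
    for gname, (start, end) in genomic.items():
        if end - start <= 0:
            continue  # zero-length intron (or degenerate exon annotation)
        spans.append(RegionSpan(label_map[gname], e.chrom, start, end, e.strand))
    return spans


def _region_span(event: ASEvent, region_label: str) -> RegionSpan | None:
    for span in event_regions(event):
        if span.label == region_label:
            return span
    if region_label not in REGION_LABELS:
        raise KeyError(f"unknown region label {region_label!r}")
    return None  # region degenerate for this event


def events_with_peak(
    events: Sequence[ASEvent], peaks: Sequence[Peak], region_label: str
) -> list[ASEvent]:
    """Events having >= 1 same-strand, >=1-bp peak overlap in the named region."""
    lookup = _IntervalLookup((p.chrom, p.start, p.end, p.strand) for p in peaks)
    out = []
    for ev in events:
        span = _region_span(ev, region_label)
        if span is not None and lookup.overlaps(span.chrom, span.start, span.end, span.strand):
            out.append(ev)
    return out


def _filter_direction(
    events: Sequence[ASEvent], direction: str, convention: SignConvention
) -> list[ASEvent]:
    if direction == "all":
        return list(events)
    if direction not in ("included", "excluded"):
        raise ValueError(f"unknown direction {direction!r}")
    return [
        ev
        for ev in events
        if ev.inc_level_difference != 0 and convention.direction(ev.inc_level_difference) == direction
    ]


def region_enrichment(
    sig_events: Sequence[ASEvent],
    background_events: Sequence[ASEvent],
    peaks: Sequence[Peak],
    region_label: str,
    direction: str = "all",
    convention: SignConvention = SignConvention(),
) -> EnrichmentResult:
    """Hypergeometric enrichment of peak-bearing events among the selected set."""
    selected = _filter_direction(sig_events, direction, convention)
    n_bg = len(background_events)
    n_sel = len(selected)
    if n_sel == 0:
        raise ValueError(f"no selected events for direction {direction!r}")
    k_bg = len(events_with_peak(background_events, peaks, region_label))
    k_sel = len(events_with_peak(selected, peaks, region_label))
    p = hypergeom_sf(n_bg, k_bg, n_sel, k_sel)
    if k_bg == 0:
        fold, defined = float("nan"), False
    else:
        fold = (k_sel / n_sel) / (k_bg / n_bg)
        defined = True
    return EnrichmentResult(region_label, direction, n_bg, k_bg, n_sel, k_sel, fold, p, defined)


def positional_profile(
    sig_events: Sequence[ASEvent],
    background_events: Sequence[ASEvent],
    peaks: Sequence[Peak],
    convention: SignConvention = SignConvention(),
) -> list[EnrichmentResult]:
    """Enrichment for each of the five sub-regions x {included, excluded},
    plus the junction span over all significant events."""
    if len(sig_events) == 0:
        raise ValueError("empty significant event set")
    results = []
    for region in REGION_LABELS[:5]:
        for direction in ("included", "excluded"):
            results.append(
                region_enrichment(
                    sig_events, background_events, peaks, region, direction, convention
                )
            )
    results.append(
        region_enrichment(sig_events, background_events, peaks, "junction_span", "all", convention)
    )
    return results


def profile_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def _windowed_span(event: ASEvent, region_label: str, window_bp: int) -> RegionSpan | None:
    """Restrict an intron span to the window adjacent to the alternative exon."""
    span = _region_span(event, region_label)
    if span is None:
        return None
    if region_label not in ("upstream_intron", "downstream_intron"):
        raise ValueError("windowing applies to intron regions only")
    length = span.end - span.start
    if window_bp >= length:
        return span
    # which genomic end of this intron touches the alternative exon?
    if span.start == event.alt_exon_end:  # intron genomically right of alt exon
        return RegionSpan(span.label, span.chrom, span.start, span.start + window_bp, span.strand)
    # intron genomically left of alt exon
    return RegionSpan(span.label, span.chrom, span.end - window_bp, span.end, span.strand)


def proximal_window_enrichment(
    sig_events: Sequence[ASEvent],
    background_events: Sequence[ASEvent],
    peaks: Sequence[Peak],
    region_label: str,
    window_bp: int,
    direction: str = "all",
    convention: SignConvention = SignConvention(),
) -> EnrichmentResult:
    """Enrichment restricted to the intron window bordering the alternative exon."""
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    selected = _filter_direction(sig_events, direction, convention)
    if not selected:
        raise ValueError(f"no selected events for direction {direction!r}")
    lookup = _IntervalLookup((p.chrom, p.start, p.end, p.strand) for p in peaks)

    def count_hits(events: Sequence[ASEvent]) -> int:
        hits = 0
        for ev in events:
            span = _windowed_span(ev, region_label, window_bp)
            if span is not None and lookup.overlaps(span.chrom, span.start, span.end, span.strand):
                hits += 1
        return hits

    n_bg, n_sel = len(background_events), len(selected)
    k_bg, k_sel = count_hits(background_events), count_hits(selected)
    p = hypergeom_sf(n_bg, k_bg, n_sel, k_sel)
    if k_bg == 0:
        fold, defined = float("nan"), False
    else:
        fold = (k_sel / n_sel) / (k_bg / n_bg)
        defined = True
    return EnrichmentResult(
        f"{region_label}[{window_bp}bp]", direction, n_bg, k_bg, n_sel, k_sel, fold, p, defined
    )
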