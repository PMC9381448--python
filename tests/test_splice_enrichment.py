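"""Strand-aware event decomposition and hypergeometric peak enrichment."""

import math
from dataclasses import replace

import numpy as np
import pytest

from clipsplice.as_events import call_significant, coverage_filter, event_key
from clipsplice.clip_peaks import Peak
from clipsplice.splice_enrichment import (
    REGION_LABELS,
    event_regions,
    events_with_peak,
    positional_profile,
    proximal_window_enrichment,
    region_enrichment,
)
from clipsplice.synthetic import SimSpec, gen_peaks, gen_rmats

from conftest import make_event


def spans_by_label(ev):
    return {s.label: s for s in event_regions(ev)}


# ---------------------------------------------------------------------------
# region decomposition

def test_regions_plus_strand():
    ev = make_event(strand="+", left=(100, 200), alt=(300, 400), right=(500, 600))
    spans = spans_by_label(ev)
    assert (spans["upstream_exon"].start, spans["upstream_exon"].end) == (100, 200)
    assert (spans["upstream_intron"].start, spans["upstream_intron"].end) == (200, 300)
    assert (spans["downstream_intron"].start, spans["downstream_intron"].end) == (400, 500)
    assert (spans["junction_span"].start, spans["junction_span"].end) == (100, 600)


def test_regions_minus_strand_labels_swap():
    """On the minus strand the genomic-left flank is transcript-downstream."""
    ev = make_event(strand="-", left=(100, 200), alt=(300, 400), right=(500, 600))
    spans = spans_by_label(ev)
    assert (spans["upstream_intron"].start, spans["upstream_intron"].end) == (400, 500)
    assert (spans["downstream_exon"].start, spans["downstream_exon"].end) == (100, 200)
    assert (spans["upstream_exon"].start, spans["upstream_exon"].end) == (500, 600)


def test_regions_abutting_exons_drop_intron():
    ev = make_event(left=(100, 300), alt=(300, 400), right=(500, 600))
    assert "upstream_intron" not in spans_by_label(ev)


# ---------------------------------------------------------------------------
# events_with_peak

def test_events_with_peak_empty_and_unique_counting():
    ev = make_event()
    assert events_with_peak([ev], [], "junction_span") == []
    two_peaks = [
        Peak("chr1", 110, 130, "+", "N", 4, 4),
        Peak("chr1", 150, 170, "+", "N", 4, 4),
    ]
    assert events_with_peak([ev], two_peaks, "junction_span") == [ev]  # counted once


def test_events_with_peak_unknown_region():
    with pytest.raises(KeyError):
        events_with_peak([make_event()], [], "nonsense")


def test_events_with_peak_matches_naive_oracle(small_dataset):
    spec, events, _ = small_dataset
    cov = coverage_filter(events)
    peaks, _ = gen_peaks(cov, spec)
    for region in ("upstream_intron", "alternative_exon", "junction_span"):
        fast = {event_key(e) for e in events_with_peak(cov, peaks, region)}
        naive = set()
        for ev in cov:
            spans = [s for s in event_regions(ev) if s.label == region]
            for s in spans:
                if any(
                    p.chrom == s.chrom
                    and p.strand == s.strand
                    and p.start < s.end
                    and s.start < p.end
                    for p in peaks
                ):
                    naive.add(event_key(ev))
        assert fast == naive


def test_peak_spanning_two_events_counts_both():
    a = make_event(event_id="a", left=(100, 200), alt=(300, 400), right=(500, 600))
    b = make_event(event_id="b", left=(380, 450), alt=(460, 480), right=(500, 600))
    wide = [Peak("chr1", 395, 465, "+", "N", 4, 4)]  # a's downstream intron + b's alt exon
    assert events_with_peak([a, b], wide, "junction_span") == [a, b]


# ---------------------------------------------------------------------------
# enrichment statistics

def test_region_enrichment_known_hypergeometric():
    """N=10 background, K=4 with peaks, n=5 selected, k=4 -> P = 6/252, fold 2."""
    events = [
        make_event(event_id=str(i), left=(100 + i * 10000, 200 + i * 10000),
                   alt=(300 + i * 10000, 400 + i * 10000),
                   right=(500 + i * 10000, 600 + i * 10000),
                   fdr=0.01, dpsi=-0.5)
        for i in range(10)
    ]
    # peaks in the alternative exon of events 0-3
    peaks = [
        Peak("chr1", 310 + i * 10000, 330 + i * 10000, "+", "N", 4, 4) for i in range(4)
    ]
    res = region_enrichment(events[:5], events, peaks, "alternative_exon", "all")
    assert (res.n_background, res.k_background, res.n_selected, res.k_selected) == (10, 4, 5, 4)
    assert res.p_hypergeom == pytest.approx(6 / 252, rel=1e-12)
    assert res.fold_enrichment == pytest.approx(2.0)


def test_region_enrichment_no_hits_p_one():
    events = [make_event(event_id=str(i), fdr=0.01, dpsi=0.3) for i in range(4)]
    res = region_enrichment(events[:2], events, [], "junction_span", "all")
    assert res.p_hypergeom == 1.0
    assert not res.fold_defined


def test_region_enrichment_empty_selection_raises():
    ev = make_event(fdr=0.01, dpsi=0.3)  # excluded
    with pytest.raises(ValueError):
        region_enrichment([ev], [ev], [], "junction_span", "included")


def test_mirror_invariance():
    """Reflecting all coordinates and flipping strands leaves enrichment unchanged."""
    spec = SimSpec(seed=13, n_events=120)
    events, _ = gen_rmats(spec)
    cov = coverage_filter(events)
    sig = call_significant(cov)
    peaks, _ = gen_peaks(cov, spec)
    L = 10_000_000

    def mirror(e):
        return replace(
            e,
            strand="-" if e.strand == "+" else "+",
            left_flank_start=L - e.right_flank_end,
            left_flank_end=L - e.right_flank_start,
            alt_exon_start=L - e.alt_exon_end,
            alt_exon_end=L - e.alt_exon_start,
            right_flank_start=L - e.left_flank_end,
            right_flank_end=L - e.left_flank_start,
        )

    def mirror_peak(p):
        return Peak(p.chrom, L - p.end, L - p.start, "-" if p.strand == "+" else "+",
                    p.rbp, p.log2_fc, p.neg_log10_p)

    m_cov = [mirror(e) for e in cov]
    m_sig = [mirror(e) for e in sig]
    m_peaks = [mirror_peak(p) for p in peaks]
    for region in REGION_LABELS[:5]:
        for direction in ("included", "excluded"):
            a = region_enrichment(sig, cov, peaks, region, direction)
            b = region_enrichment(m_sig, m_cov, m_peaks, region, direction)
            assert (a.k_background, a.k_selected) == (b.k_background, b.k_selected)
            assert a.p_hypergeom == pytest.approx(b.p_hypergeom, rel=1e-12)


# ---------------------------------------------------------------------------
# positional profile

def test_positional_profile_recovers_planted_cell(small_dataset):
    spec, events, _ = small_dataset
    cov = coverage_filter(events)
    sig = call_significant(cov)
    peaks, _ = gen_peaks(cov, spec)
    prof = positional_profile(sig, cov, peaks)
    assert len(prof) == 11
    directional = [r for r in prof if r.direction != "all"]
    best = min(directional, key=lambda r: r.p_hypergeom)
    assert (best.region, best.direction) == ("upstream_intron", "included")


def test_positional_profile_strong_plant_extremely_significant():
    """>=60% planted vs 10% background with n_selected >= 50 drives P below 1e-6."""
    for seed in (31, 32, 33):
        spec = SimSpec(seed=seed, n_events=700)
        events, _ = gen_rmats(spec)
        cov = coverage_filter(events)
        sig = call_significant(cov)
        peaks, _ = gen_peaks(cov, spec)
        res = region_enrichment(sig, cov, peaks, "upstream_intron", "included")
        assert res.n_selected >= 50
        assert res.p_hypergeom < 1e-6


def test_positional_profile_uniform_peaks_calibrated():
    """Without planting, directional cells stay near their nominal false-positive
    rate and never reach planted-signal significance levels."""
    runs = 12
    n_small, n_extreme, n_cells = 0, 0, 0
    for seed in range(runs):
        spec = SimSpec(seed=100 + seed, n_events=300, peak_plant_rate=0.0)
        events, _ = gen_rmats(spec)
        cov = coverage_filter(events)
        sig = call_significant(cov)
        peaks, _ = gen_peaks(cov, spec)
        prof = positional_profile(sig, cov, peaks)
        ps = [r.p_hypergeom for r in prof if r.direction != "all"]
        n_cells += len(ps)
        n_small += sum(p <= 0.05 for p in ps)
        n_extreme += min(ps) < 1e-4
    assert n_small / n_cells < 0.10  # per-cell rate near the nominal 5%
    assert n_extreme <= 1  # no null run mimics a planted signal


def test_positional_profile_empty_sig_raises(small_dataset):
    spec, events, _ = small_dataset
    cov = coverage_filter(events)
    with pytest.raises(ValueError):
        positional_profile([], cov, [])


# ---------------------------------------------------------------------------
# proximal windows

def test_window_covering_intron_equals_full_region():
    ev = make_event(fdr=0.01, dpsi=-0.3)
    peaks = [Peak("chr1", 210, 230, "+", "N", 4, 4)]  # upstream intron
    full = region_enrichment([ev], [ev], peaks, "upstream_intron", "all")
    windowed = proximal_window_enrichment([ev], [ev], peaks, "upstream_intron", 10_000, "all")
    assert windowed.k_selected == full.k_selected
    assert windowed.p_hypergeom == pytest.approx(full.p_hypergeom)


def test_window_anchored_at_alt_exon_border():
    """Peaks near the 3' end of the upstream intron are caught by a proximal
    window but not by one anchored at the far end."""
    # + strand: upstream intron is [200, 300); proximal = [250, 300) for 50 bp
    ev = make_event(fdr=0.01, dpsi=-0.3)
    proximal_peak = [Peak("chr1", 280, 295, "+", "N", 4, 4)]
    distal_peak = [Peak("chr1", 205, 220, "+", "N", 4, 4)]
    res_prox = proximal_window_enrichment([ev], [ev], proximal_peak, "upstream_intron", 50, "all")
    res_dist = proximal_window_enrichment([ev], [ev], distal_peak, "upstream_intron", 50, "all")
    assert res_prox.k_selected == 1
    assert res_dist.k_selected == 0


def test_window_minus_strand_proximity():
    """On the minus strand the upstream intron borders the alt exon genomically right."""
    ev = make_event(strand="-", fdr=0.01, dpsi=-0.3)
    # upstream intron = [400, 500); proximal 50bp = [400, 450)
    near = [Peak("chr1", 405, 420, "-", "N", 4, 4)]
    far = [Peak("chr1", 470, 490, "-", "N", 4, 4)]
    assert proximal_window_enrichment([ev], [ev], near, "upstream_intron", 50, "all").k_selected == 1
    assert proximal_window_enrichment([ev], [ev], far, "upstream_intron", 50, "all").k_selected == 0


def test_window_zero_raises():
    ev = make_event(fdr=0.01, dpsi=-0.3)
    with pytest.raises(ValueError):
        proximal_window_enrichment([ev], [ev], [], "upstream_intron", 0, "all")
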