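"""Seeded generators for every pipeline input, with planted recoverable truth.

Each generator emulates the statistical structure of one input the
pipeline consumes -- not the upstream assays themselves:

* ``gen_rmats``   -- cassette-exon tables with per-replicate junction
  counts, a configurable fraction of events carrying real dPSI effects,
  P from a two-sample location test on per-replicate PSI and BH FDR.
* ``gen_peaks``   -- CLIP peaks: background peaks scattered over junction
  spans plus peaks planted into a chosen sub-region of a chosen event
  subset, with enrichment scores drawn above the significance cutoffs.
* ``gen_lfq``     -- LFQ intensity matrices with a planted insoluble set.
* ``gen_mn_cohort`` -- per-neuron MFI tables with patient-level technical
  scaling and TDP-43-status-dependent effects.
* ``gen_expression`` -- NOVA1/STMN2 tables with disease-only correlation
  and a planted STMN2-low subgroup.
* ``gen_sequences`` -- foreground sequences with planted motifs over a
  uniform-random background.

Every generator is deterministic under a fixed :class:`SimSpec`: the
single global seed expands into independent per-component child streams
through :class:`numpy.random.SeedSequence`, so each sub-generator is
reproducible on its own.  Truth tables record every planted structure so
recall and false-discovery can be computed without reading generator
internals.

The generator's P values come from a simple Welch test on per-replicate
PSI estimates, not from a splicing-specific likelihood model: the
pipeline only consumes the table's columns, so the generator's
statistical fidelity matters only for the calibration tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .as_events import ASEvent, SignConvention, call_significant, event_key
from .clip_peaks import Peak
from .splice_enrichment import event_regions
from scipy.stats import ttest_ind

from .stats import benjamini_hochberg

__all__ = [
    "SimSpec",
    "gen_rmats",
    "gen_peaks",
    "gen_signature_family",
    "SIGNATURE_PATTERNS",
    "gen_lfq",
    "gen_mn_cohort",
    "gen_expression",
    "gen_sequences",
    "write_fasta",
    "read_fasta",
]

# fixed derivation rule: component name -> child index off the global seed
_COMPONENT_IDS = {
    "rmats": 1,
    "peaks": 2,
    "lfq": 3,
    "mn_cohort": 4,
    "expression": 5,
    "sequences": 6,
}


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic study; defaults mirror the study design.

    Sample sizes follow the source study where it states them (6 vs 6 LFQ
    samples, 4 replicates per RNA-seq group, 9 sALS / 7 Ctrl postmortem
    donors); effect and noise levels are fixed at values that give the
    screens realistic, not saturating, power.
    """

    seed: int = 0
    # seed of the event-coordinate universe; datasets sharing coord_seed
    # describe the same cassette exons (joinable keys) with independent
    # counts and effects.  None: derived from `seed`.
    coord_seed: int | None = None

    # rMATS generator
    n_events: int = 1000
    n_reps_g1: int = 4
    n_reps_g2: int = 4
    read_depth: int = 100
    effect_fraction: float = 0.2
    dpsi_effect: float = 0.3
    psi_concentration: float = 100.0  # beta concentration of replicate PSI
    low_coverage_fraction: float = 0.05
    low_coverage_depth: int = 5

    # peak generator
    peak_background_rate: float = 0.1
    peak_plant_rate: float = 0.6
    planted_region: str = "upstream_intron"
    planted_direction: str = "included"  # included | excluded | all
    peak_width: int = 40
    min_log2_fc: float = 3.0
    min_neg_log10_p: float = 3.0

    # LFQ generator
    n_proteins: int = 1000
    n_lfq_target: int = 6
    n_lfq_control: int = 6
    n_lfq_hits: int = 50
    lfq_log2_effect: float = 2.0
    lfq_noise_sd: float = 0.5
    lfq_dropout: float = 0.0

    # MN cohort generator
    n_ctrl_patients: int = 7
    n_sals_patients: int = 9
    neurons_per_patient: int = 20
    patient_scale_sd: float = 0.5  # lognormal sd of per-patient technical factor
    patient_bio_sd: float = 0.15  # donor-level biological variability (NOVA1, TDP43)
    tubulin_bio_sd: float = 0.03  # TUBB3 is structurally stable across donors
    neuron_shared_noise_sd: float = 0.12  # per-neuron brightness, shared by channels
    neuron_noise_sd: float = 0.06  # channel-specific residual per neuron
    nuclear_lost_fraction: float = 0.4
    cyto_nova1_effect: float = 1.5  # sALS nuclear_retained vs Ctrl, cytoplasmic NOVA1
    nuclear_nova1_effect: float = 0.7  # nuclear_lost vs retained, nuclear NOVA1
    nuclear_tdp43_effect: float = 0.3

    # expression generator
    n_expr_datasets: int = 2
    n_expr_ctrl: int = 15
    n_expr_als: int = 20
    expr_rho: float = 0.7
    stmn2_low_fraction: float = 0.25

    # sequence generator
    n_fg_seqs: int = 500
    n_bg_seqs: int = 500
    seq_length: int = 50
    motif: str = "TCAT"

    def rng(self, component: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _COMPONENT_IDS[component]])
        )


# ---------------------------------------------------------------------------
# rMATS-dialect cassette events

def gen_rmats(spec: SimSpec) -> tuple[list[ASEvent], pd.DataFrame]:
    """Generate cassette-exon events plus a truth table.

    Per event: group PSI means are drawn, a configured fraction receives
    a planted |dPSI| effect (sign random, so planted events split between
    included and excluded in the target condition); replicate PSIs are
    beta-distributed around the group mean, junction counts binomial at
    the configured depth, and the table's P/FDR come from Welch's test on
    the replicate PSI estimates with BH correction.
    """
    if spec.n_events < 1:
        raise ValueError("n_events must be >= 1")
    for rate in (spec.effect_fraction, spec.low_coverage_fraction):
        if not 0 <= rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
    rng = spec.rng("rmats")
    coord_seed = spec.seed if spec.coord_seed is None else spec.coord_seed
    rng_coord = np.random.default_rng(np.random.SeedSequence([int(coord_seed), 7]))
    chroms = ("chr1", "chr2")
    inc_len, skip_len = 198, 99
    cursor = {c: 10_000 for c in chroms}

    truth_rows = []
    raw = []
    for i in range(spec.n_events):
        chrom = chroms[i % len(chroms)]
        strand = "+" if rng_coord.random() < 0.5 else "-"
        lf_len, ae_len, rf_len = rng_coord.integers(80, 300, size=3)
        up_int, dn_int = rng_coord.integers(300, 2000, size=2)
        start = cursor[chrom]
        lf = (start, start + lf_len)
        ae = (lf[1] + up_int, lf[1] + up_int + ae_len)
        rf = (ae[1] + dn_int, ae[1] + dn_int + rf_len)
        cursor[chrom] = rf[1] + int(rng_coord.integers(500, 2000))

        psi_base = rng.uniform(0.1, 0.9)
        has_effect = rng.random() < spec.effect_fraction
        if has_effect:
            sign = 1 if rng.random() < 0.5 else -1
            # target-group PSI shifted; clip into (0,1)
            psi_g2 = float(np.clip(psi_base + sign * spec.dpsi_effect, 0.02, 0.98))
        else:
            psi_g2 = psi_base
        psi_g1 = psi_base

        depth = spec.low_coverage_depth if rng.random() < spec.low_coverage_fraction else spec.read_depth

        def replicate_counts(psi_mean: float, n: int):
            c = spec.psi_concentration
            psis = rng.beta(psi_mean * c, (1 - psi_mean) * c, size=n)
            # length-weighted inclusion probability for junction reads
            p_inc = psis * inc_len / (psis * inc_len + (1 - psis) * skip_len)
            ijc = rng.binomial(depth, p_inc)
            sjc = depth - ijc
            psi_hat = (ijc / inc_len) / (ijc / inc_len + sjc / skip_len)
            return ijc, sjc, psi_hat

        ijc1, sjc1, psi_hat1 = replicate_counts(psi_g1, spec.n_reps_g1)
        ijc2, sjc2, psi_hat2 = replicate_counts(psi_g2, spec.n_reps_g2)
        dpsi = float(psi_hat1.mean() - psi_hat2.mean())
        raw.append(
            dict(
                event_id=str(i),
                chrom=chrom,
                strand=strand,
                lf=lf,
                ae=ae,
                rf=rf,
                ijc1=ijc1,
                sjc1=sjc1,
                ijc2=ijc2,
                sjc2=sjc2,
                psi1=psi_hat1,
                psi2=psi_hat2,
                dpsi=dpsi,
            )
        )
        truth_rows.append(
            dict(
                event_id=str(i),
                planted_effect=has_effect,
                true_dpsi=psi_g1 - psi_g2,
                depth=depth,
                low_coverage=(depth == spec.low_coverage_depth),
            )
        )

    # vectorised Welch's test on replicate PSI estimates across all events
    psi1 = np.stack([r["psi1"] for r in raw])
    psi2 = np.stack([r["psi2"] for r in raw])
    degenerate = (np.ptp(psi1, axis=1) == 0) & (np.ptp(psi2, axis=1) == 0)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = ttest_ind(psi1, psi2, axis=1, equal_var=False)
    pvals = np.asarray(pvals, dtype=float)
    pvals[degenerate | ~np.isfinite(pvals)] = 1.0
    for r, p in zip(raw, pvals):
        r["p"] = float(p)
    fdr = benjamini_hochberg(pvals)
    events = []
    for r, q in zip(raw, fdr):
        events.append(
            ASEvent(
                event_id=r["event_id"],
                gene_id=f"GENE{r['event_id']}",
                gene_symbol=f"G{r['event_id']}",
                chrom=r["chrom"],
                strand=r["strand"],
                alt_exon_start=r["ae"][0],
                alt_exon_end=r["ae"][1],
                left_flank_start=r["lf"][0],
                left_flank_end=r["lf"][1],
                right_flank_start=r["rf"][0],
                right_flank_end=r["rf"][1],
                ijc_g1=tuple(int(v) for v in r["ijc1"]),
                sjc_g1=tuple(int(v) for v in r["sjc1"]),
                ijc_g2=tuple(int(v) for v in r["ijc2"]),
                sjc_g2=tuple(int(v) for v in r["sjc2"]),
                inc_form_len=inc_len,
                skip_form_len=skip_len,
                p_value=float(r["p"]),
                fdr=float(q),
                inc_level_g1=tuple(round(float(v), 6) for v in r["psi1"]),
                inc_level_g2=tuple(round(float(v), 6) for v in r["psi2"]),
                inc_level_difference=round(r["dpsi"], 6),
            )
        )
    truth = pd.DataFrame(truth_rows)
    truth["event_key"] = [event_key(ev) for ev in events]
    return events, truth


# ---------------------------------------------------------------------------
# CLIP peaks

def gen_peaks(
    events: Sequence[ASEvent],
    spec: SimSpec,
    rbp: str = "NOVA1",
    planted_keys: frozenset[str] | None = None,
) -> tuple[list[Peak], pd.DataFrame]:
    """Scatter background peaks over junction spans and plant peaks into the
    configured sub-region of the configured event subset.

    The planted subset is the significant events (default thresholds) in
    the configured dPSI direction; each draws a peak with probability
    ``peak_plant_rate``, entirely inside the named region.  All peaks get
    enrichment scores above the significance cutoffs and carry the strand
    of their event.
    """
    rng = spec.rng("peaks")
    convention = SignConvention()
    if planted_keys is not None:
        target = {id(e) for e in events if event_key(e) in planted_keys}
    else:
        sig = call_significant(list(events))
        if spec.planted_direction == "all":
            target = {id(e) for e in sig}
        elif spec.planted_direction in ("included", "excluded"):
            target = {
                id(e)
                for e in sig
                if e.inc_level_difference != 0
                and convention.direction(e.inc_level_difference) == spec.planted_direction
            }
        else:
            raise ValueError(f"unknown planted_direction {spec.planted_direction!r}")

    peaks: list[Peak] = []
    truth_rows = []

    def draw_scores():
        return (
            float(rng.uniform(spec.min_log2_fc + 0.5, spec.min_log2_fc + 5.0)),
            float(rng.uniform(spec.min_neg_log10_p + 0.5, spec.min_neg_log10_p + 10.0)),
        )

    def place_in(chrom, start, end, strand):
        width = min(spec.peak_width, end - start)
        pos = int(rng.integers(start, max(start + 1, end - width + 1)))
        fc, nlp = draw_scores()
        return Peak(chrom, pos, pos + width, strand, rbp, fc, nlp)

    def place_at_site(span, ev):
        # a binding site is a fixed position: anchor introns at the boundary
        # adjacent to the alternative exon, exons at their center, with a
        # small jitter, so replicate peak sets overlap like real eCLIP reps
        width = min(spec.peak_width, span.end - span.start)
        if "intron" in span.label:
            anchor = span.end if span.end <= ev.alt_exon_start else span.start
        else:
            anchor = (span.start + span.end) // 2
        jitter = int(rng.integers(-10, 11))
        pos = int(np.clip(anchor - width // 2 + jitter, span.start, span.end - width))
        fc, nlp = draw_scores()
        return Peak(span.chrom, pos, pos + width, span.strand, rbp, fc, nlp)

    for ev in events:
        spans = {s.label: s for s in event_regions(ev)}
        planted = False
        background = False
        if id(ev) in target and spec.planted_region in spans and rng.random() < spec.peak_plant_rate:
            peaks.append(place_at_site(spans[spec.planted_region], ev))
            planted = True
        if rng.random() < spec.peak_background_rate:
            s = spans["junction_span"]
            peaks.append(place_in(s.chrom, s.start, s.end, s.strand))
            background = True
        truth_rows.append(
            dict(
                event_key=event_key(ev),
                eligible=id(ev) in target,
                planted_peak=planted,
                background_peak=background,
            )
        )
    return peaks, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# coordinated multi-dataset signature family

SIGNATURE_PATTERNS = {
    # dataset -> planted dPSI sign per pattern; magnitude fixed below.
    # LOF: disease exclusion agrees with knockout, opposes overexpression.
    "LOF": {"ALS1": 1, "ALS2": 1, "ALS3": 1, "ALS4": 1, "SPG11": 0, "NOVA1_OE": -1, "NOVA1_KO": 1},
    "GOF": {"ALS1": -1, "ALS2": -1, "ALS3": -1, "ALS4": -1, "SPG11": 0, "NOVA1_OE": -1, "NOVA1_KO": 1},
    "ALS1_specific": {"ALS1": 1, "ALS2": 0, "ALS3": 0, "ALS4": 0, "SPG11": 0, "NOVA1_OE": 0, "NOVA1_KO": 0},
    "ALS2_specific": {"ALS1": 0, "ALS2": -1, "ALS3": 0, "ALS4": 0, "SPG11": 0, "NOVA1_OE": 0, "NOVA1_KO": 0},
    "ALS34_shared": {"ALS1": 0, "ALS2": 0, "ALS3": 1, "ALS4": 1, "SPG11": 0, "NOVA1_OE": 0, "NOVA1_KO": 0},
    "SPG11_shared": {"ALS1": 1, "ALS2": 1, "ALS3": 1, "ALS4": 1, "SPG11": 1, "NOVA1_OE": 0, "NOVA1_KO": 0},
    "OE_only": {"ALS1": 1, "ALS2": 1, "ALS3": 0, "ALS4": 0, "SPG11": 0, "NOVA1_OE": 1, "NOVA1_KO": 0},
    "weak_mixed": {"ALS1": 1, "ALS2": -1, "ALS3": 1, "ALS4": -1, "SPG11": 0, "NOVA1_OE": 0, "NOVA1_KO": 0},
}


def gen_signature_family(
    spec: SimSpec,
    n_per_cluster: int = 60,
    dpsi_magnitude: float = 0.15,
    pattern_noise_sd: float = 0.03,
) -> tuple[dict[str, dict[str, ASEvent]], list[str], pd.DataFrame, list[Peak]]:
    """Multi-dataset family with planted splicing signatures and CLIP peaks.

    Events share one coordinate universe across four disease datasets, one
    unrelated-disease control, and the two perturbation datasets.  Eight
    event groups carry the dPSI patterns in :data:`SIGNATURE_PATTERNS`
    (|dPSI| = ``dpsi_magnitude`` plus noise); the LOF group additionally
    receives peaks in its upstream introns via :func:`gen_peaks`.

    Returns (datasets keyed like rMATS tables, anchor names, truth table
    mapping event keys to pattern names, thresholded peak list).
    """
    rng = spec.rng("rmats")  # pattern noise rides on the event stream
    base_events, _ = gen_rmats(replace(spec, effect_fraction=0.0))
    base_events = [e for e in base_events if all(t >= 10 for t in e.sample_totals)]
    patterns = list(SIGNATURE_PATTERNS)
    needed = n_per_cluster * len(patterns)
    if len(base_events) < needed:
        raise ValueError(
            f"need {needed} coverage-passed events, generator produced {len(base_events)}"
        )
    datasets: dict[str, dict[str, ASEvent]] = {name: {} for name in SIGNATURE_PATTERNS["LOF"]}
    anchors = ["ALS1", "ALS2", "ALS3", "ALS4"]
    truth_rows = []
    for idx, ev in enumerate(base_events):
        key = event_key(ev)
        group = patterns[idx // n_per_cluster] if idx < needed else None
        truth_rows.append({"event_key": key, "pattern": group or "null"})
        for ds in datasets:
            if group is None:
                dpsi = float(rng.normal(0.0, 0.01))
                fdr = 0.8
            else:
                sign = SIGNATURE_PATTERNS[group][ds]
                dpsi = float(sign * dpsi_magnitude + rng.normal(0.0, pattern_noise_sd))
                fdr = 0.001 if abs(dpsi) > 0.1 else 0.8
            datasets[ds][key] = replace(
                ev, inc_level_difference=max(-1.0, min(1.0, dpsi)), fdr=fdr, p_value=fdr
            )
    truth = pd.DataFrame(truth_rows)
    lof_keys = frozenset(truth.loc[truth.pattern == "LOF", "event_key"])
    peaks, _ = gen_peaks(base_events, spec, rbp="NOVA1", planted_keys=lof_keys)
    return datasets, anchors, truth, peaks


# ---------------------------------------------------------------------------
# LFQ matrix

def gen_lfq(spec: SimSpec) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """LFQ intensity matrix (proteins x samples), group labels, truth table.

    Lognormal intensities (base log2 level ~ N(20, 2) per protein), the
    first ``n_lfq_hits`` proteins get a +``lfq_log2_effect`` shift in the
    target group, replicate noise is lognormal with sd ``lfq_noise_sd``
    (log2 scale), and entries drop to 0 with probability ``lfq_dropout``.
    """
    rng = spec.rng("lfq")
    n = spec.n_proteins
    cols = [f"ALS_{i+1}" for i in range(spec.n_lfq_target)] + [
        f"Ctrl_{i+1}" for i in range(spec.n_lfq_control)
    ]
    groups = pd.Series(
        ["ALS"] * spec.n_lfq_target + ["Ctrl"] * spec.n_lfq_control, index=cols, name="group"
    )
    base = rng.normal(20.0, 2.0, size=n)
    is_hit = np.zeros(n, dtype=bool)
    is_hit[: spec.n_lfq_hits] = True
    log2 = np.tile(base[:, None], (1, len(cols)))
    log2[is_hit, : spec.n_lfq_target] += spec.lfq_log2_effect
    log2 = log2 + rng.normal(0.0, spec.lfq_noise_sd, size=log2.shape)
    intensities = np.exp2(log2)
    dropout = rng.random(size=log2.shape) < spec.lfq_dropout
    intensities[dropout] = 0.0
    proteins = [f"P{i:04d}" for i in range(n)]
    df = pd.DataFrame(intensities, index=pd.Index(proteins, name="protein"), columns=cols)
    truth = pd.DataFrame({"protein": proteins, "planted_hit": is_hit}).set_index("protein")
    return df, groups, truth


# ---------------------------------------------------------------------------
# MN cohort

def gen_mn_cohort(spec: SimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-neuron MFI table plus per-patient truth.

    Compartment-level expected intensities are drawn per neuron, a shared
    per-patient lognormal technical factor scales every channel, and the
    soma MFI is computed as the area-weighted mixture of nucleus,
    lipofuscin-free cytoplasm, and lipofuscin, so the conservation
    identity holds exactly.  Planted biology: cytoplasmic NOVA1 is raised
    in sALS neurons that retain nuclear TDP-43, nuclear NOVA1 and nuclear
    TDP-43 are reduced in neurons that lost nuclear TDP-43.
    """
    rng = spec.rng("mn_cohort")
    base = {  # channel -> (cytoplasm, nucleus, lipofuscin) expected MFI
        "NOVA1": (40.0, 120.0, 60.0),
        "TDP43": (30.0, 150.0, 60.0),
        "TUBB3": (200.0, 60.0, 80.0),
    }
    rows = []
    patients = [("Ctrl", f"Ctrl_{i+1}") for i in range(spec.n_ctrl_patients)] + [
        ("sALS", f"sALS_{i+1}") for i in range(spec.n_sals_patients)
    ]
    truth_rows = []
    for cohort, pid in patients:
        scale = float(rng.lognormal(0.0, spec.patient_scale_sd))
        # per-channel biological level of this donor; NOT removed by
        # tubulin normalization (it is channel-specific, not technical)
        bio = {
            ch: float(
                rng.lognormal(0.0, spec.tubulin_bio_sd if ch == "TUBB3" else spec.patient_bio_sd)
            )
            for ch in base
        }
        truth_rows.append(
            {"patient_id": pid, "cohort": cohort, "technical_scale": scale, **{
                f"bio_{ch}": bio[ch] for ch in base}}
        )
        for j in range(spec.neurons_per_patient):
            area_soma = float(rng.normal(2500.0, 500.0))
            area_soma = max(area_soma, 600.0)
            area_nuc = float(np.clip(rng.normal(0.22, 0.04), 0.1, 0.35)) * area_soma
            area_lip = float(np.clip(rng.normal(0.05, 0.02), 0.0, 0.12)) * area_soma
            if cohort == "sALS" and rng.random() < spec.nuclear_lost_fraction:
                status = "nuclear_lost"
            else:
                status = "nuclear_retained"
            brightness = float(rng.lognormal(0.0, spec.neuron_shared_noise_sd))
            rec = {
                "neuron_id": f"{pid}_n{j+1}",
                "patient_id": pid,
                "cohort": cohort,
                "tdp43_status": status,
                "area_soma": round(area_soma, 2),
                "area_nucleus": round(area_nuc, 2),
                "area_lipofuscin": round(area_lip, 2),
            }
            for ch, (cyt0, nuc0, lip0) in base.items():
                cyt, nuc, lip = (v * bio[ch] for v in (cyt0, nuc0, lip0))
                if ch == "NOVA1":
                    if cohort == "sALS" and status == "nuclear_retained":
                        cyt *= spec.cyto_nova1_effect
                    if status == "nuclear_lost":
                        nuc *= spec.nuclear_nova1_effect
                if ch == "TDP43" and status == "nuclear_lost":
                    nuc *= spec.nuclear_tdp43_effect
                noise = rng.lognormal(0.0, spec.neuron_noise_sd, size=3) * brightness
                cyt, nuc, lip = cyt * noise[0] * scale, nuc * noise[1] * scale, lip * noise[2] * scale
                a_cyt = area_soma - area_nuc - area_lip
                soma = (cyt * a_cyt + nuc * area_nuc + lip * area_lip) / area_soma
                rec[f"mfi_soma_{ch}"] = soma
                rec[f"mfi_nucleus_{ch}"] = nuc
                rec[f"mfi_lipofuscin_{ch}"] = lip if area_lip > 0 else 0.0
            rows.append(rec)
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# expression tables

def gen_expression(spec: SimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NOVA1/STMN2 expression per sample with ALS-only correlation.

    Controls draw independent latent normals; ALS samples draw from a
    bivariate normal with correlation ``expr_rho``; a planted fraction of
    ALS samples additionally shift the STMN2 latent down 3 control SDs
    (and NOVA1 down 1 SD), creating the STMN2-low subgroup with reduced
    NOVA1.  Values are exponentiated to positive expression levels per
    dataset with dataset-specific scales.
    """
    rng = spec.rng("expression")
    rows, truth_rows = [], []
    for d in range(spec.n_expr_datasets):
        ds = f"DS{d+1}"
        scale_n, scale_s = float(rng.uniform(3, 6)), float(rng.uniform(4, 7))
        for i in range(spec.n_expr_ctrl):
            zn, zs = rng.normal(size=2)
            rows.append(
                dict(sample=f"{ds}_Ctrl_{i+1}", dataset=ds, group="Ctrl",
                     nova1=float(np.exp(scale_n + 0.3 * zn)), stmn2=float(np.exp(scale_s + 0.3 * zs)))
            )
            truth_rows.append(dict(sample=f"{ds}_Ctrl_{i+1}", planted_low=False))
        cov = np.array([[1.0, spec.expr_rho], [spec.expr_rho, 1.0]])
        L = np.linalg.cholesky(cov)
        for i in range(spec.n_expr_als):
            z = L @ rng.normal(size=2)
            low = rng.random() < spec.stmn2_low_fraction
            if low:
                z = z + np.array([-1.0, -3.0])
            rows.append(
                dict(sample=f"{ds}_ALS_{i+1}", dataset=ds, group="ALS",
                     nova1=float(np.exp(scale_n + 0.3 * z[0])), stmn2=float(np.exp(scale_s + 0.3 * z[1])))
            )
            truth_rows.append(dict(sample=f"{ds}_ALS_{i+1}", planted_low=bool(low)))
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# sequences

def gen_sequences(spec: SimSpec) -> tuple[list[str], list[str], pd.DataFrame]:
    """Foreground sequences with one planted motif each; uniform background."""
    rng = spec.rng("sequences")
    bases = np.array(list("ACGT"))
    motif = spec.motif.upper().replace("U", "T")
    if len(motif) > spec.seq_length:
        raise ValueError("motif longer than sequence length")

    def random_seq() -> str:
        return "".join(rng.choice(bases, size=spec.seq_length))

    fg, truth_rows = [], []
    for i in range(spec.n_fg_seqs):
        s = list(random_seq())
        pos = int(rng.integers(0, spec.seq_length - len(motif) + 1))
        s[pos : pos + len(motif)] = motif
        fg.append("".join(s))
        truth_rows.append(dict(seq_index=i, motif=motif, position=pos))
    bg = [random_seq() for _ in range(spec.n_bg_seqs)]
    return fg, bg, pd.DataFrame(truth_rows)


def write_fasta(seqs: Sequence[str], path: str | Path, prefix: str = "seq") -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f">{prefix}{i}\n{s}\n")


def read_fasta(path: str | Path) -> list[str]:
    seqs, cur = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                    cur = []
            elif line:
                cur.append(line)
    if cur:
        seqs.append("".join(cur))
    return seqs
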