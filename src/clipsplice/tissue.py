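"""Single-neuron fluorescence quantification and expression z-score analysis.

Postmortem motor neurons are measured per compartment (soma, nucleus,
lipofuscin) in several channels.  The lipofuscin-corrected cytoplasmic
mean fluorescence intensity (MFI) is

    MFI_cyt = (MFI_soma * A_soma - MFI_nuc * A_nuc - MFI_lip * A_lip) / A_cyt

with A_cyt = A_soma - A_nuc - A_lip.  To compare neurons across
individuals, channel MFIs are normalized to the beta-III-tubulin (TUBB3)
MFI of the lipofuscin-free soma (which still includes the nucleus),
cancelling patient-level multiplicative factors such as postmortem
interval and fixation differences.

The expression arm converts NOVA1/STMN2 levels to control-anchored
z-scores per dataset and classes samples with STMN2 z < -2 as STMN2-low,
a transcript-level proxy for lost nuclear TDP-43 function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, kruskal_wallis, pairwise_ranksum, sign_flip_test, spearman

__all__ = [
    "MNRecord",
    "mfi_cytoplasm",
    "soma_filter",
    "tubulin_normalize",
    "interindividual_variance_reduction",
    "matched_tdp43_comparison",
    "expression_zscores",
    "stmn2_grouping",
    "nova1_stmn2_correlation",
    "records_from_frame",
]

CHANNELS = ("NOVA1", "TDP43", "TUBB3")


@dataclass(frozen=True)
class MNRecord:
    """One neuron's areas (um^2) and per-channel compartment MFIs."""

    neuron_id: str
    patient_id: str
    cohort: str  # Ctrl | sALS
    tdp43_status: str  # nuclear_retained | nuclear_lost
    area_soma: float
    area_nucleus: float
    area_lipofuscin: float
    mfi_soma: dict = field(default_factory=dict)  # channel -> MFI
    mfi_nucleus: dict = field(default_factory=dict)
    mfi_lipofuscin: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.area_soma, self.area_nucleus, self.area_lipofuscin) < 0:
            raise ValueError(f"neuron {self.neuron_id}: negative area")
        if self.area_nucleus + self.area_lipofuscin > self.area_soma:
            raise ValueError(f"neuron {self.neuron_id}: compartments exceed soma area")

    @property
    def area_cytoplasm(self) -> float:
        return self.area_soma - self.area_nucleus - self.area_lipofuscin


def mfi_cytoplasm(record: MNRecord, channel: str, clamp: bool = True) -> tuple[float, bool]:
    """Lipofuscin-corrected cytoplasmic MFI for one channel.

    Returns (value, clamped): negative results (measurement noise) are
    clamped to 0 with the flag set.  Raises when the cytoplasmic area is
    not positive.
    """
    a_cyt = record.area_cytoplasm
    if a_cyt <= 0:
        raise ValueError(f"neuron {record.neuron_id}: non-positive cytoplasmic area")
    total = record.mfi_soma[channel] * record.area_soma
    total -= record.mfi_nucleus[channel] * record.area_nucleus
    if record.area_lipofuscin > 0:
        total -= record.mfi_lipofuscin[channel] * record.area_lipofuscin
    value = total / a_cyt
    if value < 0 and clamp:
        return 0.0, True
    return value, False


def soma_filter(records: Sequence[MNRecord], min_area: float = 1000.0) -> list[MNRecord]:
    """Keep neurons with soma area strictly greater than min_area (um^2)."""
    return [r for r in records if r.area_soma > min_area]


def _tubulin_denominator(record: MNRecord) -> float:
    """TUBB3 MFI of the lipofuscin-free soma (nucleus included)."""
    area = record.area_soma - record.area_lipofuscin
    if area <= 0:
        raise ValueError(f"neuron {record.neuron_id}: empty lipofuscin-free soma")
    total = record.mfi_soma["TUBB3"] * record.area_soma
    if record.area_lipofuscin > 0:
        total -= record.mfi_lipofuscin["TUBB3"] * record.area_lipofuscin
    return total / area


def tubulin_normalize(record: MNRecord, channel: str, compartment: str) -> float:
    """Channel MFI in a compartment divided by the TUBB3 lipofuscin-free-soma MFI.

    ``compartment`` is one of nucleus | cytoplasm | soma | lipofuscin_free_soma.
    """
    denom = _tubulin_denominator(record)
    if denom == 0:
        raise ValueError(f"neuron {record.neuron_id}: zero tubulin denominator")
    if compartment == "nucleus":
        num = record.mfi_nucleus[channel]
    elif compartment == "cytoplasm":
        num, _ = mfi_cytoplasm(record, channel)
    elif compartment == "soma":
        num = record.mfi_soma[channel]
    elif compartment == "lipofuscin_free_soma":
        area = record.area_soma - record.area_lipofuscin
        total = record.mfi_soma[channel] * record.area_soma
        if record.area_lipofuscin > 0:
            total -= record.mfi_lipofuscin[channel] * record.area_lipofuscin
        num = total / area
    else:
        raise ValueError(f"unknown compartment {compartment!r}")
    return num / denom


def _compartment_mfi(record: MNRecord, channel: str, compartment: str) -> float:
    if compartment == "nucleus":
        return record.mfi_nucleus[channel]
    if compartment == "cytoplasm":
        return mfi_cytoplasm(record, channel)[0]
    if compartment == "soma":
        return record.mfi_soma[channel]
    raise ValueError(f"unknown compartment {compartment!r}")


def interindividual_variance_reduction(
    records: Sequence[MNRecord], channel: str, compartment: str
) -> float:
    """Percent reduction in across-patient relative variance from tubulin normalization.

    Per-patient means of the raw and the normalized MFI are compared via
    their relative variance (variance divided by squared mean across
    patients), which is invariant to the overall measurement scale;
    reduction = 100 * (1 - relvar_normalized / relvar_raw).  Requires
    >= 3 patients with >= 3 neurons each.
    """
    by_patient: dict[str, list[MNRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    eligible = {p: rs for p, rs in by_patient.items() if len(rs) >= 3}
    if len(eligible) < 3:
        raise ValueError("need >= 3 patients with >= 3 neurons each")
    raw_means, norm_means = [], []
    for rs in eligible.values():
        raw_means.append(np.mean([_compartment_mfi(r, channel, compartment) for r in rs]))
        norm_means.append(np.mean([tubulin_normalize(r, channel, compartment) for r in rs]))
    raw = np.asarray(raw_means)
    norm = np.asarray(norm_means)
    relvar_raw = raw.var(ddof=1) / raw.mean() ** 2
    if relvar_raw == 0:
        raise ValueError("zero across-patient variance in the raw signal")
    relvar_norm = norm.var(ddof=1) / norm.mean() ** 2
    return float(100.0 * (1.0 - relvar_norm / relvar_raw))


def matched_tdp43_comparison(
    records: Sequence[MNRecord], channel: str, compartment: str
) -> dict:
    """Within-patient comparison of neurons by TDP-43 status.

    For each patient with neurons in both classes, the median MFI per
    status is paired; significance comes from an exact sign-flip
    permutation test on the per-patient median differences
    (nuclear_lost - nuclear_retained).
    """
    by_patient: dict[str, dict[str, list[float]]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, {}).setdefault(r.tdp43_status, []).append(
            _compartment_mfi(r, channel, compartment)
        )
    pairs = {
        p: (np.median(d["nuclear_retained"]), np.median(d["nuclear_lost"]))
        for p, d in by_patient.items()
        if "nuclear_retained" in d and "nuclear_lost" in d
    }
    if len(pairs) < 3:
        raise ValueError("need >= 3 patients with neurons in both TDP-43 classes")
    diffs = [lost - retained for retained, lost in pairs.values()]
    test = sign_flip_test(diffs)
    return {
        "per_patient": {
            p: {"nuclear_retained": float(ret), "nuclear_lost": float(lost)}
            for p, (ret, lost) in pairs.items()
        },
        "mean_difference": float(np.mean(diffs)),
        "direction": "lower_in_nuclear_lost" if np.mean(diffs) < 0 else "higher_in_nuclear_lost",
        "test": test,
    }


# ---------------------------------------------------------------------------
# expression z-scores (NOVA1 / STMN2)

def expression_zscores(table: pd.DataFrame) -> pd.DataFrame:
    """Control-anchored z-scores per dataset.

    ``table`` needs columns sample, dataset, group (Ctrl/ALS), nova1,
    stmn2.  z = (value - mean_ctrl) / sd_ctrl computed within each
    dataset; raises when a dataset has < 2 controls or zero control SD.
    """
    out = table.copy()
    for col in ("z_nova1", "z_stmn2"):
        out[col] = np.nan
    for ds, sub in table.groupby("dataset"):
        ctrl = sub[sub["group"] == "Ctrl"]
        if len(ctrl) < 2:
            raise ValueError(f"dataset {ds!r}: need >= 2 controls")
        for gene in ("nova1", "stmn2"):
            mu = ctrl[gene].mean()
            sd = ctrl[gene].std(ddof=1)
            if sd == 0:
                raise ValueError(f"dataset {ds!r}: zero control SD for {gene}")
            out.loc[sub.index, f"z_{gene}"] = (sub[gene] - mu) / sd
    return out


def stmn2_grouping(zscored: pd.DataFrame, cutoff: float = -2.0) -> pd.DataFrame:
    """Class ALS samples as STMN2 low (z < cutoff, strict) or regular.

    Controls are always ``regular``.
    """
    out = zscored.copy()
    low = (out["group"] != "Ctrl") & (out["z_stmn2"] < cutoff)
    out["stmn2_class"] = np.where(low, "low", "regular")
    return out


def nova1_stmn2_correlation(records: pd.DataFrame, group: str) -> TestResult:
    """Spearman correlation of NOVA1 vs STMN2 z-scores within one group."""
    sub = records[records["group"] == group]
    if len(sub) < 3:
        raise ValueError(f"group {group!r} has < 3 records")
    return spearman(sub["z_nova1"].to_numpy(), sub["z_stmn2"].to_numpy())


def nova1_by_stmn2_class(records: pd.DataFrame) -> dict:
    """Kruskal-Wallis + pairwise rank-sum of NOVA1 z across
    {Ctrl, ALS STMN2-regular, ALS STMN2-low}."""
    groups = {
        "Ctrl": records.loc[records["group"] == "Ctrl", "z_nova1"].to_numpy(),
        "ALS_regular": records.loc[
            (records["group"] != "Ctrl") & (records["stmn2_class"] == "regular"), "z_nova1"
        ].to_numpy(),
        "ALS_low": records.loc[
            (records["group"] != "Ctrl") & (records["stmn2_class"] == "low"), "z_nova1"
        ].to_numpy(),
    }
    names = [n for n, v in groups.items() if v.size > 0]
    vals = [groups[n] for n in names]
    kw = kruskal_wallis(vals)
    pw = pairwise_ranksum(vals)
    pairwise = {
        f"{names[i]}|{names[j]}": pw[i][j].p_two_sided
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }
    return {"kruskal": kw, "pairwise_p": pairwise, "groups": names}


# ---------------------------------------------------------------------------
# frame <-> record plumbing

def records_from_frame(df: pd.DataFrame) -> list[MNRecord]:
    """Build MNRecords from a per-neuron CSV table.

    Expects columns neuron_id, patient_id, cohort, tdp43_status, area_soma,
    area_nucleus, area_lipofuscin, and mfi_<compartment>_<channel> columns.
    """
    records = []
    for _, row in df.iterrows():
        mfi_soma, mfi_nuc, mfi_lip = {}, {}, {}
        for ch in CHANNELS:
            mfi_soma[ch] = float(row[f"mfi_soma_{ch}"])
            mfi_nuc[ch] = float(row[f"mfi_nucleus_{ch}"])
            col = f"mfi_lipofuscin_{ch}"
            mfi_lip[ch] = float(row[col]) if col in row and pd.notna(row[col]) else 0.0
        records.append(
            MNRecord(
                neuron_id=str(row["neuron_id"]),
                patient_id=str(row["patient_id"]),
                cohort=str(row["cohort"]),
                tdp43_status=str(row["tdp43_status"]),
                area_soma=float(row["area_soma"]),
                area_nucleus=float(row["area_nucleus"]),
                area_lipofuscin=float(row["area_lipofuscin"]),
                mfi_soma=mfi_soma,
                mfi_nucleus=mfi_nuc,
                mfi_lipofuscin=mfi_lip,
            )
        )
    return records
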