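"""Single-neuron MFI quantification and NOVA1/STMN2 expression analysis."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from clipsplice.synthetic import SimSpec, gen_expression, gen_mn_cohort
from clipsplice.tissue import (
    MNRecord,
    expression_zscores,
    interindividual_variance_reduction,
    matched_tdp43_comparison,
    mfi_cytoplasm,
    nova1_by_stmn2_class,
    nova1_stmn2_correlation,
    records_from_frame,
    soma_filter,
    stmn2_grouping,
    tubulin_normalize,
)


def neuron(
    neuron_id="n1",
    patient="p1",
    cohort="Ctrl",
    status="nuclear_retained",
    areas=(2000.0, 500.0, 100.0),
    soma=10.0,
    nucleus=20.0,
    lipofuscin=30.0,
    tubb3=(10.0, 10.0, 10.0),
):
    a_soma, a_nuc, a_lip = areas
    return MNRecord(
        neuron_id=neuron_id,
        patient_id=patient,
        cohort=cohort,
        tdp43_status=status,
        area_soma=a_soma,
        area_nucleus=a_nuc,
        area_lipofuscin=a_lip,
        mfi_soma={"NOVA1": soma, "TDP43": soma, "TUBB3": tubb3[0]},
        mfi_nucleus={"NOVA1": nucleus, "TDP43": nucleus, "TUBB3": tubb3[1]},
        mfi_lipofuscin={"NOVA1": lipofuscin, "TDP43": lipofuscin, "TUBB3": tubb3[2]},
    )


# ---------------------------------------------------------------------------
# cytoplasmic MFI

def test_mfi_cytoplasm_worked_example():
    """(10*2000 - 20*500 - 30*100) / 1400 = 5.0"""
    val, clamped = mfi_cytoplasm(neuron(), "NOVA1")
    assert val == pytest.approx(5.0)
    assert not clamped


def test_mfi_cytoplasm_uniform_intensity_conserved():
    val, _ = mfi_cytoplasm(neuron(soma=7.0, nucleus=7.0, lipofuscin=7.0), "NOVA1")
    assert val == pytest.approx(7.0)


def test_mfi_cytoplasm_no_lipofuscin_two_term():
    n = neuron(areas=(2000.0, 500.0, 0.0), soma=10.0, nucleus=20.0)
    val, _ = mfi_cytoplasm(n, "NOVA1")
    assert val == pytest.approx((10 * 2000 - 20 * 500) / 1500)


def test_mfi_cytoplasm_negative_clamped():
    n = neuron(soma=1.0, nucleus=50.0, lipofuscin=50.0)
    val, clamped = mfi_cytoplasm(n, "NOVA1")
    assert val == 0.0 and clamped


def test_mfi_conservation_identity():
    """soma MFI x soma area decomposes exactly over the three compartments."""
    mn, _ = gen_mn_cohort(SimSpec(seed=7, n_ctrl_patients=2, n_sals_patients=2,
                                  neurons_per_patient=5))
    for rec in records_from_frame(mn):
        cyt, _ = mfi_cytoplasm(rec, "NOVA1", clamp=False)
        total = (
            cyt * rec.area_cytoplasm
            + rec.mfi_nucleus["NOVA1"] * rec.area_nucleus
            + rec.mfi_lipofuscin["NOVA1"] * rec.area_lipofuscin
        )
        assert total == pytest.approx(rec.mfi_soma["NOVA1"] * rec.area_soma, rel=1e-9)


def test_mfi_zero_cytoplasm_raises():
    n = neuron(areas=(1000.0, 900.0, 100.0))
    with pytest.raises(ValueError):
        mfi_cytoplasm(n, "NOVA1")


# ---------------------------------------------------------------------------
# soma filter

def test_soma_filter_strict_boundary():
    at = neuron(areas=(1000.0, 100.0, 0.0))
    above = neuron(areas=(1000.1, 100.0, 0.0))
    assert soma_filter([at, above]) == [above]
    assert soma_filter([]) == []


# ---------------------------------------------------------------------------
# tubulin normalization

def test_tubulin_self_normalization_is_one():
    assert tubulin_normalize(neuron(), "TUBB3", "lipofuscin_free_soma") == pytest.approx(1.0)


def test_tubulin_scale_invariance():
    n1 = neuron()
    n2 = neuron(soma=30.0, nucleus=60.0, lipofuscin=90.0, tubb3=(30.0, 30.0, 30.0))
    for comp in ("nucleus", "cytoplasm"):
        assert tubulin_normalize(n1, "NOVA1", comp) == pytest.approx(
            tubulin_normalize(n2, "NOVA1", comp)
        )


def test_variance_reduction_with_planted_patient_factors():
    """Lognormal per-patient technical factors (sd 0.5) are removed: >=50% in every run."""
    for seed in range(3):
        mn, _ = gen_mn_cohort(SimSpec(seed=seed))
        recs = [r for r in soma_filter(records_from_frame(mn)) if r.cohort == "Ctrl"]
        for comp in ("nucleus", "cytoplasm"):
            assert interindividual_variance_reduction(recs, "NOVA1", comp) >= 50


def test_variance_reduction_without_factor_near_zero():
    """No technical factor planted: reduction stays near 0 (checked at a cohort
    size where across-donor variance is stably estimable)."""
    for seed in range(3):
        mn, _ = gen_mn_cohort(
            replace(SimSpec(seed=seed), patient_scale_sd=0.0,
                    n_ctrl_patients=25, neurons_per_patient=30)
        )
        recs = [r for r in soma_filter(records_from_frame(mn)) if r.cohort == "Ctrl"]
        for comp in ("nucleus", "cytoplasm"):
            assert abs(interindividual_variance_reduction(recs, "NOVA1", comp)) < 15


def test_variance_reduction_degenerate_raises():
    base = [neuron(neuron_id=f"n{i}", patient=f"p{j}")
            for j in range(3) for i in range(3)]
    with pytest.raises(ValueError):
        interindividual_variance_reduction(base, "NOVA1", "nucleus")  # zero raw variance


# ---------------------------------------------------------------------------
# matched TDP-43 comparison

def test_matched_comparison_identical_groups_p_one():
    recs = []
    for j in range(4):
        for status in ("nuclear_retained", "nuclear_lost"):
            for i in range(3):
                recs.append(
                    neuron(neuron_id=f"p{j}{status}{i}", patient=f"p{j}",
                           cohort="sALS", status=status)
                )
    res = matched_tdp43_comparison(recs, "NOVA1", "nucleus")
    assert res["test"].p_two_sided == 1.0


def test_matched_comparison_planted_nuclear_deficit():
    """30% nuclear NOVA1 deficit in TDP-43-lost neurons: right direction, P < 0.05."""
    detected = 0
    for seed in range(5):
        mn, _ = gen_mn_cohort(
            replace(SimSpec(seed=seed), n_sals_patients=6, neurons_per_patient=20,
                    nuclear_nova1_effect=0.7)
        )
        recs = [r for r in soma_filter(records_from_frame(mn)) if r.cohort == "sALS"]
        res = matched_tdp43_comparison(recs, "NOVA1", "nucleus")
        if res["direction"] == "lower_in_nuclear_lost" and res["test"].p_two_sided < 0.05:
            detected += 1
    assert detected >= 4


def test_matched_comparison_too_few_patients():
    recs = [neuron(patient="p1", status=s) for s in ("nuclear_retained", "nuclear_lost")]
    with pytest.raises(ValueError):
        matched_tdp43_comparison(recs, "NOVA1", "nucleus")


# ---------------------------------------------------------------------------
# expression z-scores

def expr_table():
    return pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(6)],
            "dataset": ["d1"] * 6,
            "group": ["Ctrl", "Ctrl", "Ctrl", "ALS", "ALS", "ALS"],
            "nova1": [8.0, 10.0, 12.0, 9.0, 11.0, 5.0],
            "stmn2": [8.0, 10.0, 12.0, 10.0, 4.0, 2.0],
        }
    )


def test_zscore_control_anchoring():
    z = expression_zscores(expr_table())
    ctrl = z[z.group == "Ctrl"]
    assert ctrl["z_nova1"].mean() == pytest.approx(0.0, abs=1e-12)
    # ctrl stmn2: mean 10, sd 2 -> value 4 gives z = -3
    assert z.loc[z["sample"] == "s4", "z_stmn2"].iloc[0] == pytest.approx(-3.0)


def test_stmn2_grouping_strict_cutoff():
    z = expression_zscores(expr_table())
    z.loc[z["sample"] == "s3", "z_stmn2"] = -2.0  # exactly at the cutoff
    g = stmn2_grouping(z)
    assert g.loc[g["sample"] == "s3", "stmn2_class"].iloc[0] == "regular"
    assert g.loc[g["sample"] == "s4", "stmn2_class"].iloc[0] == "low"
    assert (g.loc[g.group == "Ctrl", "stmn2_class"] == "regular").all()


def test_zscore_zero_control_sd_raises():
    t = expr_table()
    t.loc[t.group == "Ctrl", "stmn2"] = 5.0
    with pytest.raises(ValueError):
        expression_zscores(t)


def test_planted_als_only_correlation():
    """Disease-only NOVA1-STMN2 coupling: strong in ALS, absent in controls."""
    hits = 0
    for seed in range(5):
        expr, _ = gen_expression(replace(SimSpec(seed=seed), n_expr_als=40,
                                         stmn2_low_fraction=0.0))
        z = stmn2_grouping(expression_zscores(expr))
        als = nova1_stmn2_correlation(z, "ALS")
        ctrl = nova1_stmn2_correlation(z, "Ctrl")
        if als.statistic > 0.4 and als.p_two_sided < 0.05 and abs(ctrl.statistic) < 0.3:
            hits += 1
    assert hits >= 4


def test_stmn2_low_group_has_reduced_nova1():
    expr, truth = gen_expression(SimSpec(seed=12, n_expr_als=60))
    z = stmn2_grouping(expression_zscores(expr))
    res = nova1_by_stmn2_class(z)
    assert "ALS_low" in res["groups"]
    low = z[(z.group == "ALS") & (z.stmn2_class == "low")]["z_nova1"].mean()
    reg = z[(z.group == "ALS") & (z.stmn2_class == "regular")]["z_nova1"].mean()
    assert low < reg


def test_correlation_undersized_group_raises():
    z = stmn2_grouping(expression_zscores(expr_table()))
    with pytest.raises(ValueError):
        nova1_stmn2_correlation(z[z.group == "Ctrl"].iloc[:2], "Ctrl")
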