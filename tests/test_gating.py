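"""Gate hierarchy: calibration, partition, monotonicity, AGAT-1 flagging."""

import pandas as pd
import pytest

from munflow import (
    agat1_stained_profile,
    h2b_kd_facs_profile,
    wt_facs_profile,
    wt_profile,
)
from munflow.classify import classify_events
from munflow.gating import (
    CalibrationError,
    GateTree,
    Gate,
    apply_gates,
    calibrate_thresholds,
    default_facs_tree,
    default_is_tree,
    fit_population_gates,
    gate_agat1,
    gate_summary,
)
from munflow.simulate import simulate_intensity_table


@pytest.fixture(scope="module")
def facs_tables():
    prof = wt_facs_profile()
    stained = simulate_intensity_table(prof, 8000, seed=31)
    control = simulate_intensity_table(prof, 1500, seed=32, unstained=True)
    return stained, control, calibrate_thresholds(control)


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def test_constant_control_threshold_is_that_constant():
    ctrl = pd.DataFrame({"calcein_intensity": [7.0] * 50,
                         "draq5_intensity": [3.0] * 50})
    thr = calibrate_thresholds(ctrl)
    assert thr["calcein_intensity"] == 7.0
    assert thr["draq5_intensity"] == 3.0


def test_quantile_definition_bounds_control_pass_rate(facs_tables):
    _, control, thr = facs_tables
    exceed = (control["calcein_intensity"] > thr["calcein_intensity"]).mean()
    assert exceed <= 0.005 + 1e-12


def test_empty_control_raises():
    with pytest.raises(CalibrationError):
        calibrate_thresholds(pd.DataFrame())


def test_thresholds_deterministic_across_runs():
    prof = wt_facs_profile()
    a = calibrate_thresholds(simulate_intensity_table(prof, 400, seed=5, unstained=True))
    b = calibrate_thresholds(simulate_intensity_table(prof, 400, seed=5, unstained=True))
    assert a == b


# ---------------------------------------------------------------------------
# hierarchy semantics
# ---------------------------------------------------------------------------

def test_event_below_draq5_threshold_reaches_no_population(facs_tables):
    stained, _, thr = facs_tables
    tree = default_facs_tree(thr)
    gated = apply_gates(stained, tree)
    below = gated[gated["draq5_intensity"] < thr["draq5_intensity"]]
    assert below["population"].isna().all()
    assert not below["double_positive"].any()


def test_population_counts_partition_double_positives(facs_tables):
    stained, _, thr = facs_tables
    gated = apply_gates(stained, default_facs_tree(thr))
    dp = int(gated["double_positive"].sum())
    labelled = int(gated["population"].notna().sum())
    ungated = int((gated["double_positive"] & gated["population"].isna()).sum())
    assert labelled + ungated == dp
    # every labelled event is double positive
    assert not (gated["population"].notna() & ~gated["double_positive"]).any()


def test_raising_thresholds_never_grows_downstream_counts(facs_tables):
    stained, _, thr = facs_tables
    base = apply_gates(stained, default_facs_tree(thr))
    hi = dict(thr)
    hi["draq5_intensity"] *= 50.0
    raised = apply_gates(stained, default_facs_tree(hi))
    assert raised["double_positive"].sum() <= base["double_positive"].sum()
    for pop in ("A", "B", "C", "D", "E"):
        assert (raised["population"] == pop).sum() <= (base["population"] == pop).sum()


def test_commuting_positivity_gates_order_invariant(facs_tables):
    stained, _, thr = facs_tables

    def tree(order):
        gates = []
        parent = None
        for ch in order:
            gates.append(Gate(name=f"{ch}_pos", parent=parent, kind="min",
                              fields=(f"{ch}_intensity",),
                              threshold=float(thr[f"{ch}_intensity"])))
            parent = f"{ch}_pos"
        return GateTree(gates=tuple(gates), double_positive_gate=parent)

    a = apply_gates(stained, tree(["calcein", "draq5"]))["double_positive"]
    b = apply_gates(stained, tree(["draq5", "calcein"]))["double_positive"]
    assert (a == b).all()


def test_facs_populations_recover_profile_mix(facs_tables):
    stained, _, thr = facs_tables
    gated = apply_gates(stained, default_facs_tree(thr))
    dp = gated[gated["double_positive"]]
    pct = {p: 100.0 * (dp["population"] == p).mean() for p in ("D", "E")}
    assert pct["E"] == pytest.approx(25.3, abs=2.5)
    assert pct["D"] == pytest.approx(14.7, abs=2.0)
    kd = apply_gates(simulate_intensity_table(h2b_kd_facs_profile(), 8000, seed=33),
                     default_facs_tree(thr))
    kdp = kd[kd["double_positive"]]
    assert 100.0 * (kdp["population"] == "E").mean() == pytest.approx(9.1, abs=1.5)


def test_gate_summary_reports_counts_and_rates(facs_tables):
    stained, _, thr = facs_tables
    tree = default_facs_tree(thr)
    gated = apply_gates(stained, tree)
    summary = gate_summary(gated, tree)
    assert summary["cells"]["count"] >= summary["singlet"]["count"]
    assert all(0.0 <= v["pass_rate"] <= 1.0 for v in summary.values())


def test_fitted_population_boxes_cover_labelled_cohort(facs_tables):
    stained, _, thr = facs_tables
    cells = stained[stained["true_class"].isin(["MoN", "MuN"])]
    boxes = fit_population_gates(cells, populations=("A", "B", "C", "D", "E"))
    gated = apply_gates(stained, default_facs_tree(thr, rects=boxes))
    dp = gated[gated["double_positive"] & gated["true_class"].eq("MoN")]
    agree = (dp["population"] == dp["true_population"]).mean()
    assert agree >= 0.95


# ---------------------------------------------------------------------------
# image-stream mode: singlet gate and the E1 control
# ---------------------------------------------------------------------------

def test_skipping_singlet_gate_grows_e_without_changing_mun_fraction(wt_run):
    feats = wt_run
    # re-gate the same features with and without doublet discrimination
    thr = {"calcein_intensity": 300.0, "draq5_intensity": 300.0}
    with_singlet = classify_events(apply_gates(feats, default_is_tree(thr)))
    e1 = classify_events(apply_gates(feats, default_is_tree(thr, skip_singlet=True)))
    n_e = (with_singlet["population"] == "E'").sum()
    n_e1 = (e1["population"] == "E'").sum()
    assert n_e1 >= n_e
    f_e = (with_singlet[(with_singlet["population"] == "E'")]["object_class"] == "MuN").mean()
    f_e1 = (e1[(e1["population"] == "E'")]["object_class"] == "MuN").mean()
    assert abs(f_e - f_e1) < 0.01  # MuNs are not excluded by the singlet gate


# ---------------------------------------------------------------------------
# AGAT-1 gate
# ---------------------------------------------------------------------------

def test_all_zero_agat1_yields_zero_positive(facs_tables):
    stained, _, thr = facs_tables
    df = stained.copy()
    df["agat1_intensity"] = 0.0
    thr2 = dict(thr, agat1_intensity=10.0)
    flagged = gate_agat1(df, thr2)
    assert flagged["agat1_positive"].sum() == 0


def test_missing_agat1_column_is_schema_error(facs_tables):
    stained, _, thr = facs_tables
    with pytest.raises(KeyError, match="agat1"):
        gate_agat1(stained.drop(columns=["agat1_intensity"]), thr)


def test_agat1_rates_recovered_among_draq5_positive():
    prof = agat1_stained_profile()
    stained = simulate_intensity_table(prof, 15000, seed=41)
    control = simulate_intensity_table(prof, 1500, seed=42, unstained=True)
    thr = calibrate_thresholds(
        control, channels=("calcein_intensity", "draq5_intensity", "agat1_intensity"))
    flagged = gate_agat1(stained, thr)
    dpos = flagged[flagged["gate_draq5_pos"]]
    overall = dpos["agat1_positive"].mean()
    assert 0.25 <= overall <= 0.30
    muns = dpos[dpos["true_class"] == "MuN"]
    assert muns["agat1_positive"].mean() == pytest.approx(0.70, abs=0.08)
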