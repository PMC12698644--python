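"""Synthetic-event generator: composition, rendering, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from munflow import wt_profile
from munflow.simulate import (
    PlacementError,
    QpcrDesign,
    GroundTruth,
    largest_remainder_counts,
    render_event,
    sample_truth,
    simulate_ct_table,
    simulate_events,
    simulate_intensity_table,
    simulate_unstained_control,
    truth_table,
    _event_roster,
)

from conftest import flood_fill_nuclearity


# ---------------------------------------------------------------------------
# profile validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("overrides, field", [
    ({"population_mix": {"B'": 0.5, "C'": 0.4, "D'": 0.05, "E'": 0.02}}, "population_mix"),
    ({"nuclearity_pmf": {1: 0.5, 2: 0.5}}, "nuclearity_pmf"),
    ({"nuclearity_pmf": {2: 0.6, 3: 0.2}}, "nuclearity_pmf"),
    ({"nucleus_diameter_range": (0.0, 3.0)}, "nucleus_diameter_range"),
    ({"nucleus_diameter_range": (3.0, 30.0)}, "nucleus_diameter_range"),
    ({"debris_fraction": 0.7, "clump_fraction": 0.5}, "debris_fraction"),
], ids=["mix-sum", "pmf-support", "pmf-sum", "nucleus-low", "nucleus-high", "fractions"])
def test_invalid_profile_names_offending_field(overrides, field):
    with pytest.raises(ValueError, match=field.split("_")[0]):
        wt_profile(**overrides)


def test_quota_allocation_matches_proportions_exactly():
    cells = 1.0 - 0.05 - 0.03
    probs = [0.05, 0.03] + [cells * p for p in (0.146, 0.146, 0.16, 0.548)]
    counts = largest_remainder_counts(50_000, probs)
    assert counts.sum() == 50_000
    # quota allocation is within one count of n*p, far inside the binomial
    # 3*sqrt(p(1-p)/n) convergence bound
    for c, p in zip(counts, probs):
        assert abs(c - 50_000 * p) <= 1.0
        assert abs(c / 50_000 - p) <= 3 * np.sqrt(p * (1 - p) / 50_000)


def test_zero_rate_profile_contains_no_muns_or_clumps():
    prof = wt_profile(muns_fraction_in_E=0.0, clump_fraction=0.0)
    rng = np.random.default_rng(0)
    roster = _event_roster(prof, 2000, rng)
    classes = {c for c, _, _ in roster}
    assert "MuN" not in classes and "clump" not in classes


def test_cohort_is_reproducible_from_seed(wt_prof, tmp_path):
    a = list(simulate_events(wt_prof, 40, seed=7))
    b = list(simulate_events(wt_prof, 40, seed=7))
    assert truth_table([t for t, _ in a]).equals(truth_table([t for t, _ in b]))
    for (_, ia), (_, ib) in zip(a, b):
        assert np.array_equal(ia.pixels, ib.pixels)
    c = list(simulate_events(wt_prof, 40, seed=8))
    assert not all(np.array_equal(x.pixels, y.pixels) for (_, x), (_, y) in zip(a, c))


def test_written_cohort_roundtrips_through_tiff(wt_prof, tmp_path):
    from munflow.simulate import simulate_cohort
    from munflow.io import read_event_tiff

    table = simulate_cohort(wt_prof, 6, tmp_path, seed=3)
    assert len(table) == 6
    assert (tmp_path / "manifest.json").exists()
    truths = {t.event_id: i for t, i in simulate_events(wt_prof, 6, seed=3)}
    img = read_event_tiff(tmp_path / "events" / "ev000000.tif")
    assert np.allclose(img.pixels, truths["ev000000"].pixels)
    assert img.channel_map == truths["ev000000"].channel_map


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def test_brightfield_renders_cells_darker_fluorescence_brighter(wt_prof):
    rng = np.random.default_rng(1)
    truth = sample_truth(wt_prof, "MoN", "E'", 1, rng, "ev")
    img = render_event(truth, wt_prof.noiseless(), rng)
    bf = img.channel("BF")
    border = np.median(np.concatenate([bf[0], bf[-1]]))
    cy, cx = (int(c) for c in truth.body_centers_px[0])
    assert bf[cy, cx] < border  # absorbance-like
    cal = img.channel("Calcein")
    assert cal[cy, cx] > np.median(np.concatenate([cal[0], cal[-1]]))
    assert (img.pixels >= 0).all()


def test_single_nucleus_renders_one_blob(wt_prof):
    rng = np.random.default_rng(2)
    prof = wt_prof.noiseless()
    truth = GroundTruth(
        event_id="ev", true_class="MoN", population="E'", nuclearity=1,
        cell_diameter_um=9.0, body_diameters_um=(9.0,),
        body_centers_px=((32.0, 32.0),), nucleus_diameters_um=(3.0,),
        nucleus_centers_px=((32.0, 32.0),), nucleus_body=(0,),
        nucleus_halo=(False,),
    )
    img = render_event(truth, prof, rng)
    assert flood_fill_nuclearity(img) == 1


def test_eight_nuclei_render_as_eight_disjoint_blobs_in_one_body(wt_prof):
    rng = np.random.default_rng(3)
    prof = wt_prof.noiseless()
    truth = sample_truth(prof, "MuN", "E'", 8, rng, "ev")
    img = render_event(truth, prof, rng)
    assert flood_fill_nuclearity(img) == 8
    # a single calcein body despite eight nuclei
    cal = img.channel("Calcein")
    mask = cal > 0.5 * cal.max()
    _, n = ndimage.label(mask)
    assert n == 1


def test_touching_clump_is_connected_in_bf_but_two_bodies(wt_prof):
    rng = np.random.default_rng(4)
    prof = wt_prof.noiseless().model_copy(update={"clump_body_range": (2, 2)})
    truth = sample_truth(prof, "clump", "E'", 0, rng, "ev")
    img = render_event(truth, prof, rng)
    bf = img.channel("BF")
    dark = bf < np.median(np.concatenate([bf[0], bf[-1]])) - 20
    _, n = ndimage.label(dark)
    assert n == 1  # union connected in brightfield
    assert len(truth.body_centers_px) == 2


def test_rendering_fidelity_blob_count_equals_nuclearity(wt_prof):
    prof = wt_prof.noiseless()
    mism = 0
    total = 0
    for truth, img in simulate_events(prof, 200, seed=11):
        if truth.true_class == "debris":
            continue
        total += 1
        if flood_fill_nuclearity(img) != truth.nuclearity:
            mism += 1
    assert total > 100
    assert mism == 0


def test_impossible_nucleus_placement_raises():
    prof = wt_profile()
    truth = GroundTruth(
        event_id="ev", true_class="MoN", population="E'", nuclearity=1,
        cell_diameter_um=8.0, body_diameters_um=(8.0,),
        body_centers_px=((32.0, 32.0),), nucleus_diameters_um=(3.5,),
        nucleus_centers_px=((32.0, 40.0),),  # spills outside an 8 um body
        nucleus_body=(0,), nucleus_halo=(False,),
    )
    with pytest.raises(PlacementError):
        render_event(truth, prof, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# unstained control
# ---------------------------------------------------------------------------

def test_unstained_control_calibrates_below_stained_population(wt_prof):
    ctrl = simulate_unstained_control(wt_prof, 300, seed=5)
    hi_ctrl = np.quantile(ctrl["calcein_intensity"], 0.995)
    stained = simulate_intensity_table(wt_prof, 2000, seed=6)
    cells = stained[stained["true_class"] != "debris"]
    lo_stained = np.quantile(cells["calcein_intensity"], 0.05)
    assert hi_ctrl < lo_stained


def test_unstained_control_rejects_empty_and_is_deterministic(wt_prof):
    with pytest.raises(ValueError):
        simulate_unstained_control(wt_prof, 0)
    a = simulate_unstained_control(wt_prof, 25, seed=9)
    b = simulate_unstained_control(wt_prof, 25, seed=9)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# Ct table simulation
# ---------------------------------------------------------------------------

def _design(**kw):
    base = dict(base_ct={"Smedwi1": 24.0, "GST1": 22.0},
                fold_changes={"H2B_KD": {"Smedwi1": 0.1, "GST1": 3.0}})
    base.update(kw)
    return QpcrDesign(**base)


def test_ct_table_null_design_yields_unit_folds():
    from munflow.qpcr import delta_delta_ct

    design = _design(fold_changes={"H2B_KD": {"Smedwi1": 1.0, "GST1": 1.0}})
    table = simulate_ct_table(design, reps=3, noise_sd=0.0, seed=1)
    res = delta_delta_ct(table, "Ef2", "WT")
    assert np.allclose(res["fold_change"], 1.0)


def test_ct_table_encodes_folds_exactly_at_zero_noise():
    from munflow.qpcr import delta_delta_ct

    table = simulate_ct_table(_design(), reps=3, noise_sd=0.0, seed=1)
    res = delta_delta_ct(table, "Ef2", "WT").set_index(["condition", "gene"])
    assert res.loc[("H2B_KD", "Smedwi1"), "fold_change"] == pytest.approx(0.1)
    assert res.loc[("H2B_KD", "GST1"), "fold_change"] == pytest.approx(3.0)


def test_ct_table_deterministic_and_validates_folds():
    a = simulate_ct_table(_design(), reps=3, seed=4)
    b = simulate_ct_table(_design(), reps=3, seed=4)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ValueError, match="fold change"):
        _design(fold_changes={"KD": {"Smedwi1": 0.0}})
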