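"""Proportion summaries, ANOVA/Tukey, t-tests and Holm adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from munflow.popstats import (
    anova_tukey,
    holm_adjust,
    summarize,
    two_sided_t,
)


def _cohort_frame(condition, replicate, n_mun, n_mon, pop="E'"):
    rows = []
    for i in range(n_mun):
        rows.append({"object_class": "MuN", "nuclei_count": 2, "population": pop,
                     "double_positive": True})
    for i in range(n_mon):
        rows.append({"object_class": "MoN", "nuclei_count": 1, "population": pop,
                     "double_positive": True})
    df = pd.DataFrame(rows)
    df["condition"] = condition
    df["replicate"] = replicate
    return df


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_identical_kd_and_wt_give_relative_one():
    frames = [_cohort_frame(c, r, 10, 490)
              for c in ("WT", "KD") for r in (1, 2, 3)]
    summary = summarize(pd.concat(frames, ignore_index=True), control="WT")
    rel = summary.relative.set_index("condition")["mun_proportion_relative"]
    assert rel["KD"] == pytest.approx(1.0)
    assert rel["WT"] == pytest.approx(1.0)
    per_rep = summary.per_replicate
    assert np.allclose(per_rep["mun_proportion"], 0.02)
    assert (per_rep["frac_2nuc"] == 1.0).all()


def test_relative_ratio_tracks_depletion():
    frames = [_cohort_frame("WT", r, 20, 480) for r in (1, 2, 3)]
    frames += [_cohort_frame("KD", r, 8, 492) for r in (1, 2, 3)]
    summary = summarize(pd.concat(frames, ignore_index=True), control="WT")
    rel = summary.relative.set_index("condition")["mun_proportion_relative"]
    assert rel["KD"] == pytest.approx(0.4)


def test_missing_control_condition_raises():
    df = _cohort_frame("KD", 1, 5, 95)
    with pytest.raises(KeyError, match="WT"):
        summarize(df, control="WT")


# ---------------------------------------------------------------------------
# Holm–Bonferroni
# ---------------------------------------------------------------------------

def test_holm_hand_computed_sequence():
    assert np.allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])
    # classic step-down: k hypotheses, smallest p is fully Bonferroni-scaled
    assert np.allclose(holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=12))
def test_holm_properties(ps):
    adj = holm_adjust(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-15)   # adjusted >= raw
    assert np.all(adj <= 1.0 + 1e-15)
    order = np.argsort(ps)
    assert np.all(np.diff(adj[order]) >= -1e-12)   # monotone in raw order
    # smallest raw p gets the full Bonferroni factor
    i = order[0]
    assert adj[i] == pytest.approx(min(1.0, ps[i] * len(ps)))


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------

def test_anova_requires_two_groups_and_two_values():
    with pytest.raises(ValueError):
        anova_tukey({"a": [1, 2, 3]})
    with pytest.raises(ValueError):
        anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


def test_anova_tukey_zero_variance_separated_means():
    reports = anova_tukey({"g1": [1.0, 1.0, 1.0],
                           "g2": [1.0, 1.0, 1.0],
                           "g3": [5.0, 5.0, 5.0]})
    omni = reports[0]
    assert omni.significant and omni.flags == "degenerate-variance"
    pairwise = {r.name: r for r in reports[1:]}
    assert not pairwise["tukey:g1 vs g2"].significant
    assert pairwise["tukey:g1 vs g3"].significant
    assert pairwise["tukey:g2 vs g3"].significant


def test_anova_matches_scipy_on_regular_data():
    from scipy import stats

    rng = np.random.default_rng(3)
    groups = {k: rng.normal(loc, 1.0, size=6)
              for k, loc in [("a", 0.0), ("b", 0.5), ("c", 2.0)]}
    omni = anova_tukey(groups)[0]
    ref = stats.f_oneway(*groups.values())
    assert omni.statistic == pytest.approx(ref.statistic)
    assert omni.p_value == pytest.approx(ref.pvalue)


def test_tukey_matches_scipy_tukey_hsd():
    from scipy import stats

    rng = np.random.default_rng(4)
    groups = {k: rng.normal(loc, 1.0, size=5)
              for k, loc in [("a", 0.0), ("b", 1.0), ("c", 3.0)]}
    ours = {r.groups: r.p_value for r in anova_tukey(groups)[1:]}
    ref = stats.tukey_hsd(*groups.values())
    keys = list(groups)
    for i in range(3):
        for j in range(i + 1, 3):
            assert ours[(keys[i], keys[j])] == pytest.approx(
                ref.pvalue[i, j], abs=1e-9)


def test_anova_type_one_error_rate_near_alpha():
    """Null simulation oracle: three groups from one normal distribution
    reject at ~5% under alpha = 0.05."""
    rng = np.random.default_rng(12345)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        groups = {k: rng.normal(0.0, 1.0, size=5) for k in ("a", "b", "c")}
        rejections += anova_tukey(groups)[0].significant
    assert 0.03 <= rejections / reps <= 0.07


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------

def test_identical_groups_give_zero_statistic():
    rep = two_sided_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert rep.statistic == pytest.approx(0.0)
    assert not rep.significant


def test_degenerate_variance_paths_are_flagged():
    same = two_sided_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert same.p_value == 1.0 and same.flags == "degenerate-variance"
    diff = two_sided_t([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], welch=True)
    assert diff.significant and diff.flags == "degenerate-variance"


def test_t_test_type_one_error_rate_near_alpha():
    rng = np.random.default_rng(54321)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        rep = two_sided_t(rng.normal(size=6), rng.normal(size=6))
        rejections += rep.significant
    assert 0.03 <= rejections / reps <= 0.07


def test_equal_rate_regeneration_cohorts_rarely_reject():
    """Stability reproduction: replicate MuN proportions measured from
    equal-rate cohorts (binomial measurement model at the pipeline's
    double-positive depth) are non-significant in >= 90% of seeded reps."""
    conditions = ["no_amp", "0hpa", "24hpa", "72hpa", "120hpa"]
    n_dp, p = 4600, 0.011
    non_sig = 0
    reps = 100
    for seed in range(reps):
        rng = np.random.default_rng(1000 + seed)
        groups = {c: rng.binomial(n_dp, p, size=3) / n_dp for c in conditions}
        non_sig += not anova_tukey(groups)[0].significant
    assert non_sig / reps >= 0.90
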