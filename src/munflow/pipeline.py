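"""End-to-end in-memory pipeline: simulate -> features -> gate -> classify.

This is the composition layer the CLI, the tests and the acceptance script
share.  Thresholds are calibrated from a simulated unstained control of the
same profile before gating, exactly as the instrument workflow gates stained
samples against an unstained sample.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import pandas as pd

from .classify import classify_events
from .gating import GateTree, apply_gates, calibrate_thresholds, default_is_tree
from .morphometry import MorphometryParams, compute_event_features
from .profiles import SimProfile
from .simulate import simulate_events, simulate_unstained_control, truth_table

__all__ = ["run_cohort", "run_replicates"]


def run_cohort(
    profile: SimProfile,
    n_events: int,
    seed: Optional[int] = None,
    morph_params: Optional[MorphometryParams] = None,
    tree: Optional[GateTree] = None,
    thresholds: Optional[Dict[str, float]] = None,
    control_n: int = 500,
    skip_singlet: bool = False,
    keep_truth: bool = True,
) -> pd.DataFrame:
    """Simulate one cohort and push it through the full analysis chain.

    Returns the classified event table; ground-truth columns (``true_*``)
    are merged in when ``keep_truth`` so recovery can be scored.
    """
    params = morph_params or MorphometryParams()
    seed = profile.seed if seed is None else int(seed)
    if thresholds is None:
        control = simulate_unstained_control(
            profile, control_n, seed=seed + 1_000_003, morph_params=params)
        thresholds = calibrate_thresholds(control)
    if tree is None:
        tree = default_is_tree(thresholds, skip_singlet=skip_singlet)

    truths = []
    rows = []
    for truth, image in simulate_events(profile, n_events, seed=seed):
        truths.append(truth)
        rows.append(compute_event_features(image, params))
    feats = pd.DataFrame(rows)
    gated = apply_gates(feats, tree)
    classified = classify_events(gated, component_cap=params.component_cap)
    if keep_truth:
        classified = classified.merge(truth_table(truths), on="event_id", how="left")
    return classified


def run_replicates(
    profile: SimProfile,
    n_events: int,
    n_replicates: int,
    base_seed: int,
    condition: Optional[str] = None,
    **kwargs,
) -> pd.DataFrame:
    """Run ``n_replicates`` independent cohorts of one condition and stack
    them with condition/replicate columns (seeds: base_seed + replicate)."""
    frames: List[pd.DataFrame] = []
    for rep in range(1, n_replicates + 1):
        df = run_cohort(profile, n_events, seed=base_seed + rep, **kwargs)
        df["condition"] = condition or profile.name
        df["replicate"] = rep
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
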