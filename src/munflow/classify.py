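"""Object classification: MoN, MuN (2nuc / >2nuc) or clump.

The instrument workflow this package emulates resolved multinucleated cells
from clumps of mononucleated cells by visual inspection of the brightfield
and Calcein images.  Here that step is an explicit, deterministic rule set
over the measured features:

1. no nuclei resolved                       -> unresolved
2. >= 2 calcein bodies each holding nuclei  -> clump (multi-body rule)
3. >= 2 nuclei in one compact body          -> MuN
4. >= 2 nuclei but low solidity or overflow -> clump (shape rule)
5. exactly 1 nucleus                        -> MoN

Events whose extra calcein components hold no nuclei (attached anucleate
debris) stay MuN candidates: only nucleated bodies trigger the multi-body
rule, and sub-minimum attachments are not counted as bodies at all.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

__all__ = ["classify_events", "classify_event", "nuclearity_split",
           "UndefinedSplitError", "DEFAULT_SOLIDITY_MIN"]

DEFAULT_SOLIDITY_MIN = 0.85


class UndefinedSplitError(ValueError):
    """The 2nuc vs >2nuc split is undefined (no MuNs in the cohort)."""


def classify_events(
    features: pd.DataFrame,
    solidity_min: float = DEFAULT_SOLIDITY_MIN,
    component_cap: int = 8,
) -> pd.DataFrame:
    """Classify every event row; adds ``object_class``, ``nuclearity_class``
    and ``rationale_flags`` columns.  Deterministic and row-wise, so
    permuting the input permutes the output identically."""
    df = features.copy()
    nuclei = df["nuclei_count"].to_numpy(dtype=int)
    bodies = df["n_nucleated_bodies"].to_numpy(dtype=int)
    solidity = df["solidity"].to_numpy(dtype=float)
    overflow = df["overflow"].to_numpy(dtype=bool)

    multi_body = bodies >= 2
    low_solidity = solidity < solidity_min
    conditions = [
        nuclei == 0,
        multi_body,
        (nuclei >= 2) & ~overflow & ~low_solidity,
        nuclei >= 2,  # low solidity or overflow
        nuclei == 1,
    ]
    choices = ["unresolved", "clump", "MuN", "clump", "MoN"]
    object_class = np.select(conditions, choices, default="unresolved")

    nuclearity_class = np.full(len(df), "n/a", dtype=object)
    is_mun = object_class == "MuN"
    nuclearity_class[is_mun & (nuclei == 2)] = "2nuc"
    nuclearity_class[is_mun & (nuclei >= 3) & (nuclei <= component_cap)] = ">2nuc"
    nuclearity_class[(object_class == "MoN")] = "1"

    flags = np.full(len(df), "", dtype=object)
    flags[multi_body] = "multi-body"
    shape_clump = (object_class == "clump") & ~multi_body
    flags[shape_clump & low_solidity] = "low-solidity"
    flags[shape_clump & overflow & ~low_solidity] = "overflow"

    df["object_class"] = object_class
    df["nuclearity_class"] = nuclearity_class
    df["rationale_flags"] = flags
    return df


def classify_event(features_row: pd.Series, **kwargs) -> pd.Series:
    """Single-event convenience wrapper around :func:`classify_events`."""
    return classify_events(features_row.to_frame().T, **kwargs).iloc[0]


def nuclearity_split(classified: pd.DataFrame) -> Tuple[float, float]:
    """Proportions of 2-nucleated vs >2-nucleated cells within the MuN pool.

    Raises :class:`UndefinedSplitError` when the cohort holds no MuNs
    instead of silently returning 0/0.
    """
    muns = classified[classified["object_class"] == "MuN"]
    if len(muns) == 0:
        raise UndefinedSplitError("no MuNs in cohort; 2nuc/>2nuc split undefined")
    frac2 = float((muns["nuclei_count"] == 2).mean())
    return frac2, 1.0 - frac2
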