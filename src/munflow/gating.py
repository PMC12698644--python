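"""Hierarchical fluorescence gating of event feature tables.

Events are pushed through an ordered tree of gates rooted at "all events";
each gate is a predicate over feature columns (1-D threshold or axis-aligned
rectangle in log10 intensity space), evaluated only for events that passed
the parent gate.  Leaf gates carry population labels: the image-stream
hierarchy partitions Calcein+Draq5+ double positives into the B'..E'
quadrants of the (log10 Calcein, log10 Draq5) plane, the sorter-style
hierarchy into populations A..E.  Positivity thresholds are calibrated as an
upper quantile of an unstained control sample.

Rectangles are half-open (lower edge inclusive, upper edge exclusive), so
populations sharing an edge are mutually exclusive and the population counts
partition the double-positive pool exactly.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

__all__ = [
    "Gate",
    "GateTree",
    "CalibrationError",
    "calibrate_thresholds",
    "apply_gates",
    "gate_summary",
    "gate_agat1",
    "default_is_tree",
    "default_facs_tree",
    "fit_population_gates",
    "DEFAULT_CHANNELS",
]

DEFAULT_CHANNELS = ("calcein_intensity", "draq5_intensity")

#: default population rectangles, log10 integrated intensity.
#: Image-stream mode: quadrants at (calcein 4.05, draq5 3.95) — midway
#: between the low/high staining modes of the default intensity model after
#: mask losses.  Sorter mode: a low-Draq5 band split in two plus a
#: high-Draq5 band split in three.
IS_RECTS: Dict[str, Tuple[Tuple[float, float], Tuple[float, float]]] = {
    "B'": ((-math.inf, 4.05), (-math.inf, 3.95)),
    "C'": ((4.05, math.inf), (-math.inf, 3.95)),
    "D'": ((-math.inf, 4.05), (3.95, math.inf)),
    "E'": ((4.05, math.inf), (3.95, math.inf)),
}
FACS_RECTS: Dict[str, Tuple[Tuple[float, float], Tuple[float, float]]] = {
    "A": ((-math.inf, 3.95), (-math.inf, 3.70)),
    "B": ((3.95, math.inf), (-math.inf, 3.70)),
    "C": ((-math.inf, 3.60), (3.70, math.inf)),
    "D": ((3.60, 4.25), (3.70, math.inf)),
    "E": ((4.25, math.inf), (3.70, math.inf)),
}


class CalibrationError(ValueError):
    """Thresholds cannot be calibrated (e.g. empty control table)."""


class Gate(BaseModel):
    """One node of the gate tree."""

    name: str
    parent: Optional[str] = None
    kind: str = Field(pattern="^(min|max|rect)$")
    fields: Tuple[str, ...]
    bounds: Tuple[Tuple[float, float], ...] = ()
    threshold: float = 0.0
    log10: bool = False
    population: Optional[str] = None

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        for f in self.fields:
            if f not in df.columns:
                raise KeyError(f"gate {self.name!r}: unknown feature field {f!r}")
        if self.kind == "min":
            return df[self.fields[0]].to_numpy(dtype=float) >= self.threshold
        if self.kind == "max":
            return df[self.fields[0]].to_numpy(dtype=float) <= self.threshold
        # rect: half-open [lo, hi) box, optionally in log10 space
        ok = np.ones(len(df), dtype=bool)
        for f, (lo, hi) in zip(self.fields, self.bounds):
            v = df[f].to_numpy(dtype=float)
            if self.log10:
                with np.errstate(divide="ignore", invalid="ignore"):
                    v = np.where(v > 0, np.log10(np.clip(v, 1e-300, None)), -np.inf)
            ok &= (v >= lo) & (v < hi)
        return ok


class GateTree(BaseModel):
    """Ordered gates + the leaf-gate -> population mapping."""

    gates: Tuple[Gate, ...]
    population_map: Dict[str, str] = Field(default_factory=dict)
    double_positive_gate: Optional[str] = None
    skip_singlet: bool = False

    def model_post_init(self, __context) -> None:
        names = set()
        for g in self.gates:
            if g.parent is not None and g.parent not in names:
                raise ValueError(f"gate {g.name!r} references unknown parent {g.parent!r}")
            names.add(g.name)
        for leaf in self.population_map:
            if leaf not in names:
                raise ValueError(f"population_map references unknown gate {leaf!r}")


def calibrate_thresholds(
    control: pd.DataFrame,
    quantile: float = 0.995,
    channels: Sequence[str] = DEFAULT_CHANNELS,
) -> Dict[str, float]:
    """Per-channel positivity threshold = given quantile of the unstained
    control intensities.

    The quantile uses the conservative ("higher") order statistic, so the
    fraction of control events strictly above the threshold never exceeds
    1 - quantile.
    """
    if control is None or len(control) == 0:
        raise CalibrationError("control table is empty")
    out = {}
    for ch in channels:
        if ch not in control.columns:
            raise CalibrationError(f"control table lacks channel column {ch!r}")
        out[ch] = float(np.quantile(control[ch].to_numpy(dtype=float), quantile,
                                    method="higher"))
    return out


def _population_gates(
    rects: Mapping[str, Tuple[Tuple[float, float], Tuple[float, float]]],
    parent: str,
    x_field: str,
    y_field: str,
) -> Tuple[Tuple[Gate, ...], Dict[str, str]]:
    gates = []
    pop_map = {}
    for pop, (xr, yr) in rects.items():
        gname = f"pop_{pop}"
        gates.append(Gate(name=gname, parent=parent, kind="rect",
                          fields=(x_field, y_field), bounds=(xr, yr),
                          log10=True, population=pop))
        pop_map[gname] = pop
    return tuple(gates), pop_map


def default_is_tree(
    thresholds: Mapping[str, float],
    rects: Optional[Mapping[str, Tuple[Tuple[float, float], Tuple[float, float]]]] = None,
    skip_singlet: bool = False,
    focus_min: float = 2.0,
    area_min_um2: float = 12.5,
    aspect_min: float = 0.6,
    area_max_um2: Optional[float] = None,
) -> GateTree:
    """The image-stream hierarchy: focus -> debris removal -> singlet ->
    Calcein+ -> Draq5+ -> population quadrants B'..E'.

    ``skip_singlet`` reproduces the E1 control, where doublet
    discrimination is omitted to show that large MuNs are not excluded by
    it.  The singlet gate is shape-based (aspect ratio); an optional upper
    area cut is available but off by default since MuNs are legitimately the
    largest objects in the pool.
    """
    rects = rects or IS_RECTS
    gates = [
        Gate(name="focus", kind="min", fields=("focus_score",), threshold=focus_min),
        Gate(name="cells", parent="focus", kind="min", fields=("cell_area",),
             threshold=area_min_um2),
    ]
    parent = "cells"
    if not skip_singlet:
        gates.append(Gate(name="singlet", parent=parent, kind="min",
                          fields=("aspect_ratio",), threshold=aspect_min))
        parent = "singlet"
        if area_max_um2 is not None:
            gates.append(Gate(name="singlet_area", parent=parent, kind="max",
                              fields=("cell_area",), threshold=area_max_um2))
            parent = "singlet_area"
    gates.append(Gate(name="calcein_pos", parent=parent, kind="min",
                      fields=("calcein_intensity",),
                      threshold=float(thresholds["calcein_intensity"])))
    gates.append(Gate(name="draq5_pos", parent="calcein_pos", kind="min",
                      fields=("draq5_intensity",),
                      threshold=float(thresholds["draq5_intensity"])))
    pop_gates, pop_map = _population_gates(
        rects, "draq5_pos", "calcein_intensity", "draq5_intensity")
    return GateTree(gates=tuple(gates) + pop_gates, population_map=pop_map,
                    double_positive_gate="draq5_pos", skip_singlet=skip_singlet)


def default_facs_tree(
    thresholds: Mapping[str, float],
    rects: Optional[Mapping[str, Tuple[Tuple[float, float], Tuple[float, float]]]] = None,
    skip_singlet: bool = False,
    area_min_um2: float = 12.5,
    aspect_min: float = 0.6,
) -> GateTree:
    """Sorter-style hierarchy: scatter-proxy debris gate -> singlet ->
    Calcein+ -> Draq5+ -> populations A..E (no focus gate: no images)."""
    rects = rects or FACS_RECTS
    gates = [
        Gate(name="cells", kind="min", fields=("cell_area",), threshold=area_min_um2),
    ]
    parent = "cells"
    if not skip_singlet:
        gates.append(Gate(name="singlet", parent=parent, kind="min",
                          fields=("aspect_ratio",), threshold=aspect_min))
        parent = "singlet"
    gates.append(Gate(name="calcein_pos", parent=parent, kind="min",
                      fields=("calcein_intensity",),
                      threshold=float(thresholds["calcein_intensity"])))
    gates.append(Gate(name="draq5_pos", parent="calcein_pos", kind="min",
                      fields=("draq5_intensity",),
                      threshold=float(thresholds["draq5_intensity"])))
    pop_gates, pop_map = _population_gates(
        rects, "draq5_pos", "calcein_intensity", "draq5_intensity")
    return GateTree(gates=tuple(gates) + pop_gates, population_map=pop_map,
                    double_positive_gate="draq5_pos", skip_singlet=skip_singlet)


def apply_gates(features: pd.DataFrame, tree: GateTree) -> pd.DataFrame:
    """Evaluate the tree; returns the table plus per-gate boolean columns,
    a ``double_positive`` column and the final ``population`` label
    (NA = ungated)."""
    df = features.copy()
    passed: Dict[Optional[str], np.ndarray] = {None: np.ones(len(df), dtype=bool)}
    population = np.full(len(df), None, dtype=object)
    for gate in tree.gates:
        mask = passed[gate.parent] & gate.evaluate(df)
        passed[gate.name] = mask
        df[f"gate_{gate.name}"] = mask
        if gate.name in tree.population_map:
            label = tree.population_map[gate.name]
            population = np.where(mask & pd.isna(population), label, population)
    if tree.double_positive_gate is not None:
        df["double_positive"] = passed[tree.double_positive_gate]
    else:
        df["double_positive"] = passed[tree.gates[-1].name]
    df["population"] = population
    return df


def gate_summary(gated: pd.DataFrame, tree: GateTree) -> Dict[str, Dict[str, float]]:
    """Per-gate counts and pass rates (of the parent gate's events)."""
    out = {}
    n_all = len(gated)
    for gate in tree.gates:
        n = int(gated[f"gate_{gate.name}"].sum())
        parent_n = int(gated[f"gate_{gate.parent}"].sum()) if gate.parent else n_all
        out[gate.name] = {
            "count": n,
            "pass_rate": (n / parent_n) if parent_n else 0.0,
        }
    return out


def gate_agat1(
    features: pd.DataFrame,
    thresholds: Mapping[str, float],
) -> pd.DataFrame:
    """Flag Draq5+ events whose AGAT-1 antibody intensity exceeds its
    calibrated threshold.  Requires ``agat1_intensity`` and a prior
    ``draq5_intensity`` threshold (or an existing draq5_pos gate column)."""
    if "agat1_intensity" not in features.columns:
        raise KeyError("agat1_intensity column missing from feature table")
    df = features.copy()
    if "gate_draq5_pos" in df.columns:
        draq_pos = df["gate_draq5_pos"].to_numpy(dtype=bool)
    else:
        draq_pos = (df["draq5_intensity"].to_numpy(dtype=float)
                    >= float(thresholds["draq5_intensity"]))
    thr = float(thresholds["agat1_intensity"])
    df["agat1_positive"] = draq_pos & (df["agat1_intensity"].to_numpy(dtype=float) > thr)
    df["gate_draq5_pos"] = draq_pos
    return df


def fit_population_gates(
    labelled: pd.DataFrame,
    populations: Iterable[str],
    label_col: str = "true_population",
    x_field: str = "calcein_intensity",
    y_field: str = "draq5_intensity",
    n_sd: float = 4.0,
) -> Dict[str, Tuple[Tuple[float, float], Tuple[float, float]]]:
    """Fit axis-aligned population rectangles from a labelled calibration
    cohort as mean +/- n_sd covariance-ellipse bounding boxes in log10
    space, then expand shared edges to the midpoint so the rectangles tile
    the plane without overlap along each axis pair."""
    boxes = {}
    for pop in populations:
        sub = labelled[labelled[label_col] == pop]
        if len(sub) < 5:
            raise ValueError(f"too few labelled events for population {pop!r}")
        lx = np.log10(np.clip(sub[x_field].to_numpy(dtype=float), 1e-12, None))
        ly = np.log10(np.clip(sub[y_field].to_numpy(dtype=float), 1e-12, None))
        boxes[pop] = (
            (float(lx.mean() - n_sd * lx.std()), float(lx.mean() + n_sd * lx.std())),
            (float(ly.mean() - n_sd * ly.std()), float(ly.mean() + n_sd * ly.std())),
        )
    return boxes
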