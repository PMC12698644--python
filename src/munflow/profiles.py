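"""Cohort simulation profiles.

A :class:`SimProfile` pins down everything the synthetic-event generator
needs to emulate one acquisition condition of a dissociated planarian cell
suspension on an imaging flow cytometer: the composition of the
double-positive pool over the intensity-plane populations (B'..E' for
image-stream data, A..E for sorter-style data), the share of multinucleated
cells (MuNs) inside the MuN-harbouring population, the nuclearity spectrum,
cell and nuclear size distributions, per-population staining-intensity
models and the optical noise model.

The wild-type and knockdown factory profiles encode the printed cohort
compositions this package is meant to recover: population E' holds 54.8%
of wild-type double positives (34% after histone-H2B knockdown, which
ablates neoblasts), population D' holds 16% (3.1% after knockdown), ~2% of
E' events are MuNs (~1-2% of all double positives), two thirds of MuNs are
binucleated, and the knockdown cohorts carry 0.8x (H2B) and 0.4x (Agat-1)
the wild-type MuN share of double positives.
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

from pydantic import BaseModel, Field, model_validator

IS_POPULATIONS: Tuple[str, ...] = ("B'", "C'", "D'", "E'")
FACS_POPULATIONS: Tuple[str, ...] = ("A", "B", "C", "D", "E")

#: channel roles understood by the renderer, in canonical page order
CHANNEL_ROLES = ("BF", "Calcein", "Draq5", "CellBrite", "AGAT1")


class IntensityModel(BaseModel):
    """Per-population log10-normal models of integrated staining intensity.

    Locations/scales are in log10 arbitrary units of the *integrated*
    (background-subtracted, whole-object) intensity.  The Draq5 entry is the
    per-nucleus location: a cell's total Draq5 signal scales linearly with
    its nuclearity, which is what places MuNs at the top of the
    double-positive intensity range.
    """

    calcein_log10: Dict[str, Tuple[float, float]]
    draq5_log10: Dict[str, Tuple[float, float]]
    agat1_positive_log10: Tuple[float, float] = (4.2, 0.15)
    # marker-negative cells carry only trace autofluorescence, well below
    # the unstained-control positivity threshold
    agat1_negative_log10: Tuple[float, float] = (1.0, 0.30)
    cellbrite_log10: Tuple[float, float] = (4.0, 0.10)


class NoiseModel(BaseModel):
    """Optical model: additive read noise, optional shot noise, backgrounds.

    ``blur_sigma_px`` is the point-spread surrogate applied to every
    channel; it is part of the rendering, not of the noise, and is kept in
    "noiseless" renders.
    """

    read_noise_sd: float = 2.0
    shot_noise: bool = True
    fluor_background: float = 5.0
    bf_background: float = 200.0
    bf_cell_depth: float = 80.0  # brightfield absorbance depth of a cell body
    bf_rim_depth: float = 40.0   # extra absorbance of each body's boundary rim
    bf_rim_width_px: float = 1.5  # rim extends inward from the body edge
    blur_sigma_px: float = 0.7

    def silenced(self) -> "NoiseModel":
        return self.model_copy(update={"read_noise_sd": 0.0, "shot_noise": False})


def default_nuclearity_pmf() -> Dict[int, float]:
    """Two thirds of MuNs are binucleated; 3..8 nuclei decay geometrically."""
    weights = {k: 0.5 ** (k - 3) for k in range(3, 9)}
    total = sum(weights.values())
    pmf = {2: 0.67}
    pmf.update({k: 0.33 * w / total for k, w in weights.items()})
    return pmf


class SimProfile(BaseModel):
    """Ground-truth statistical description of one simulated cohort."""

    name: str
    population_mix: Dict[str, float]
    debris_fraction: float = Field(0.05, ge=0.0, lt=1.0)
    clump_fraction: float = Field(0.03, ge=0.0, lt=1.0)
    mun_population: str = "E'"
    muns_fraction_in_E: float = Field(0.02, ge=0.0, le=1.0)
    nuclearity_pmf: Dict[int, float] = Field(default_factory=default_nuclearity_pmf)
    mun_diameter_mean_sd: Tuple[float, float] = (16.0, 1.0)
    mon_diameter_mean_sd: Dict[str, Tuple[float, float]] = Field(default_factory=dict)
    clump_cell_diameter_mean_sd: Tuple[float, float] = (8.5, 0.8)
    clump_population: str = "E'"
    clump_body_range: Tuple[int, int] = (2, 3)
    nucleus_diameter_range: Tuple[float, float] = (3.0, 4.0)
    intensity: IntensityModel
    noise: NoiseModel = Field(default_factory=NoiseModel)
    halo_fraction: float = Field(0.3, ge=0.0, le=1.0)
    halo_relative_intensity: float = 0.25
    halo_width_px: float = 1.0
    agat1_positive_rate: Dict[str, float] = Field(
        default_factory=lambda: {"MuN": 0.0, "other": 0.0}
    )
    internal_membrane_fraction: float = 0.5
    channels: Tuple[str, ...] = ("BF", "Calcein", "Draq5")
    pixel_size_um: float = Field(0.5, gt=0.0)
    raster_shape: Tuple[int, int] = (64, 64)
    min_separation_pad_px: float = 4.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimProfile":
        if not self.population_mix:
            raise ValueError("population_mix: at least one population is required")
        total = sum(self.population_mix.values())
        if any(v < 0 for v in self.population_mix.values()):
            raise ValueError("population_mix: proportions must be nonnegative")
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"population_mix: proportions sum to {total!r}, not 1")
        if self.debris_fraction + self.clump_fraction >= 1.0:
            raise ValueError("debris_fraction + clump_fraction must be < 1")
        if self.mun_population not in self.population_mix:
            raise ValueError(
                f"mun_population {self.mun_population!r} missing from population_mix"
            )
        pmf = self.nuclearity_pmf
        if any(k < 2 or k > 8 for k in pmf):
            raise ValueError("nuclearity_pmf: support must lie in 2..8")
        if any(v < 0 for v in pmf.values()):
            raise ValueError("nuclearity_pmf: probabilities must be nonnegative")
        if not math.isclose(sum(pmf.values()), 1.0, abs_tol=1e-9):
            raise ValueError("nuclearity_pmf: probabilities must sum to 1")
        lo, hi = self.nucleus_diameter_range
        if not 0 < lo <= hi:
            raise ValueError("nucleus_diameter_range: need 0 < low <= high")
        cell_diams = [self.mun_diameter_mean_sd[0]] + [
            m for m, _ in self.mon_diameter_mean_sd.values()
        ]
        if hi >= min(cell_diams):
            raise ValueError("nucleus_diameter_range: must be below cell diameters")
        for pop in self.population_mix:
            if pop not in self.intensity.calcein_log10:
                raise ValueError(f"intensity.calcein_log10: missing population {pop!r}")
            if pop not in self.intensity.draq5_log10:
                raise ValueError(f"intensity.draq5_log10: missing population {pop!r}")
            if pop != self.mun_population and pop not in self.mon_diameter_mean_sd:
                raise ValueError(f"mon_diameter_mean_sd: missing population {pop!r}")
        unknown = set(self.channels) - set(CHANNEL_ROLES)
        if unknown:
            raise ValueError(f"channels: unknown roles {sorted(unknown)}")
        return self

    # -- convenience -------------------------------------------------------

    @property
    def populations(self) -> Tuple[str, ...]:
        return tuple(self.population_mix)

    def noiseless(self) -> "SimProfile":
        return self.model_copy(update={"noise": self.noise.silenced()})

    def with_seed(self, seed: int) -> "SimProfile":
        return self.model_copy(update={"seed": int(seed)})

    def with_channels(self, *channels: str) -> "SimProfile":
        return self.model_copy(update={"channels": tuple(channels)})


# ---------------------------------------------------------------------------
# factory profiles (image-stream, B'..E')
# ---------------------------------------------------------------------------

_IS_INTENSITY = IntensityModel(
    calcein_log10={"B'": (3.7, 0.1), "C'": (4.5, 0.1), "D'": (3.7, 0.1), "E'": (4.5, 0.1)},
    draq5_log10={"B'": (3.6, 0.1), "C'": (3.6, 0.1), "D'": (4.4, 0.1), "E'": (4.4, 0.1)},
)

_IS_MON_DIAMETERS = {"B'": (8.0, 0.8), "C'": (9.0, 0.8), "D'": (8.5, 0.8), "E'": (10.0, 0.8)}

#: wild-type share of double positives per population; D'/E' are the printed
#: values, the unprinted remainder is split evenly between B' and C'
_WT_IS_MIX = {"B'": 0.146, "C'": 0.146, "D'": 0.16, "E'": 0.548}
_H2B_IS_MIX = {"B'": 0.3145, "C'": 0.3145, "D'": 0.031, "E'": 0.34}

_WT_MUN_SHARE_OF_DP = _WT_IS_MIX["E'"] * 0.02  # ~1.1% of double positives


def wt_profile(**overrides) -> SimProfile:
    """Wild-type image-stream cohort: ~2% MuNs within population E'."""
    kwargs = dict(
        name="WT",
        population_mix=dict(_WT_IS_MIX),
        muns_fraction_in_E=0.02,
        mon_diameter_mean_sd=dict(_IS_MON_DIAMETERS),
        intensity=_IS_INTENSITY,
    )
    kwargs.update(overrides)
    return SimProfile(**kwargs)


def h2b_kd_profile(**overrides) -> SimProfile:
    """Neoblast-ablated cohort: D' collapses to 3.1%, E' to 34%, and the
    MuN share of double positives falls to 0.8x the wild-type level."""
    f_in_e = 0.8 * _WT_MUN_SHARE_OF_DP / _H2B_IS_MIX["E'"]
    kwargs = dict(
        name="H2B_KD",
        population_mix=dict(_H2B_IS_MIX),
        muns_fraction_in_E=f_in_e,
        mon_diameter_mean_sd=dict(_IS_MON_DIAMETERS),
        intensity=_IS_INTENSITY,
    )
    kwargs.update(overrides)
    return SimProfile(**kwargs)


def agat1_kd_profile(**overrides) -> SimProfile:
    """Late-epidermal-progenitor knockdown: population mix unchanged, but
    the MuN share of double positives falls to 0.4x the wild-type level."""
    f_in_e = 0.4 * _WT_MUN_SHARE_OF_DP / _WT_IS_MIX["E'"]
    kwargs = dict(
        name="Agat1_KD",
        population_mix=dict(_WT_IS_MIX),
        muns_fraction_in_E=f_in_e,
        mon_diameter_mean_sd=dict(_IS_MON_DIAMETERS),
        intensity=_IS_INTENSITY,
    )
    kwargs.update(overrides)
    return SimProfile(**kwargs)


def regeneration_profile(hours_post_amputation: int | str, **overrides) -> SimProfile:
    """Regeneration time-point cohort.

    MuN prevalence is stable across regeneration, so these profiles differ
    from wild type only by name; they exist so that condition manifests and
    the stability statistics have distinct cohorts to chew on.
    """
    label = (
        "no_amp"
        if str(hours_post_amputation) in ("no_amp", "noamp")
        else f"regen_{int(hours_post_amputation)}hpa"
    )
    return wt_profile(name=label, **overrides)


def high_nuclearity_profile(**overrides) -> SimProfile:
    """MuN-only cohort with a uniform 2..8 nuclearity spectrum and slightly
    larger cells, used to exercise the component cap and high-nuclearity
    mask splitting with well-separated nuclei."""
    kwargs = dict(
        name="high_nuclearity",
        population_mix={"E'": 1.0},
        debris_fraction=0.0,
        clump_fraction=0.0,
        muns_fraction_in_E=1.0,
        nuclearity_pmf={k: 1.0 / 7.0 for k in range(2, 9)},
        mun_diameter_mean_sd=(17.0, 0.8),
        mon_diameter_mean_sd={},
        intensity=_IS_INTENSITY,
    )
    kwargs.update(overrides)
    return SimProfile(**kwargs)


def agat1_stained_profile(**overrides) -> SimProfile:
    """Wild-type cohort with the AGAT-1 antibody channel enabled: 70% of
    MuNs and 27% of other cells carry the late-epidermal-progenitor marker,
    which yields the ~25-30% AGAT-1+ share of Draq5+ events."""
    kwargs = dict(
        agat1_positive_rate={"MuN": 0.70, "other": 0.27},
        channels=("BF", "Calcein", "Draq5", "AGAT1"),
    )
    kwargs.update(overrides)
    return wt_profile(name="WT_agat1", **kwargs)


# ---------------------------------------------------------------------------
# factory profiles (sorter-style, A..E; intensity-only tables)
# ---------------------------------------------------------------------------

_FACS_INTENSITY = IntensityModel(
    calcein_log10={
        "A": (3.6, 0.1), "B": (4.3, 0.1), "C": (3.3, 0.1), "D": (3.9, 0.1), "E": (4.6, 0.1),
    },
    draq5_log10={
        "A": (3.3, 0.1), "B": (3.3, 0.1), "C": (4.1, 0.1), "D": (4.1, 0.1), "E": (4.3, 0.1),
    },
)

_FACS_MON_DIAMETERS = {
    "A": (8.0, 0.8), "B": (9.0, 0.8), "C": (8.0, 0.8), "D": (8.5, 0.8), "E": (10.0, 0.8),
}

_WT_FACS_MIX = {"A": 0.20, "B": 0.20, "C": 0.20, "D": 0.147, "E": 0.253}
_H2B_FACS_MIX = {"A": 0.273, "B": 0.273, "C": 0.273, "D": 0.090, "E": 0.091}


def wt_facs_profile(**overrides) -> SimProfile:
    """Wild-type sorter-style cohort: E 25.3%, D 14.7% of double positives."""
    kwargs = dict(
        name="WT_FACS",
        population_mix=dict(_WT_FACS_MIX),
        mun_population="E",
        muns_fraction_in_E=0.02,
        clump_population="E",
        mon_diameter_mean_sd=dict(_FACS_MON_DIAMETERS),
        intensity=_FACS_INTENSITY,
    )
    kwargs.update(overrides)
    return SimProfile(**kwargs)


def h2b_kd_facs_profile(**overrides) -> SimProfile:
    """H2B-knockdown sorter-style cohort: E falls to 9.1%, D to 9.0%."""
    kwargs = dict(
        name="H2B_KD_FACS",
        population_mix=dict(_H2B_FACS_MIX),
        mun_population="E",
        clump_population="E",
        muns_fraction_in_E=0.02,
        mon_diameter_mean_sd=dict(_FACS_MON_DIAMETERS),
        intensity=_FACS_INTENSITY,
    )
    kwargs.update(overrides)
    return SimProfile(**kwargs)
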