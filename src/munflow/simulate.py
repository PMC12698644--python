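"""Synthetic event generation: ground truth sampling and image rendering.

Each simulated acquisition event is a small multi-channel raster (one page
per channel: brightfield, Calcein, Draq5, optionally CellBrite membrane and
AGAT-1 antibody) plus a :class:`GroundTruth` record carrying the labels the
recovery tests grade against.  Cohort composition (debris / clumps /
population cells / MuNs / nuclearity) is allocated by largest-remainder
proportional quota and then shuffled, so a cohort's class counts match the
profile exactly while per-event attributes, geometry and noise remain
random; this is the same convention scikit-learn's synthetic generators use
and it keeps recovery experiments focused on detection error rather than
sampling error.

All randomness derives from a single integer seed through per-event
``numpy`` child streams, so cohorts are bitwise reproducible and individual
events can be re-rendered in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from .profiles import SimProfile

__all__ = [
    "EventImage",
    "GroundTruth",
    "PlacementError",
    "QpcrDesign",
    "render_event",
    "sample_truth",
    "simulate_events",
    "simulate_cohort",
    "simulate_unstained_control",
    "simulate_intensity_table",
    "simulate_ct_table",
    "truth_table",
]


class PlacementError(RuntimeError):
    """Nuclei cannot be placed inside the cell body at the requested sizes."""


@dataclass(frozen=True)
class EventImage:
    """Multi-channel pixel raster for one acquired object."""

    pixels: np.ndarray  # (n_channels, H, W) float32
    channel_map: Dict[str, int]
    pixel_size_um: float
    event_id: str

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a (channels, H, W) stack")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if len(self.channel_map) != self.pixels.shape[0]:
            raise ValueError("channel_map does not cover all pages")

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.pixels[self.channel_map[role]]
        except KeyError:
            raise KeyError(f"channel {role!r} not present in event {self.event_id}")


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side labels for one event."""

    event_id: str
    true_class: str  # MoN | MuN | clump | debris
    population: Optional[str]
    nuclearity: int
    cell_diameter_um: float  # largest body
    body_diameters_um: Tuple[float, ...]
    body_centers_px: Tuple[Tuple[float, float], ...]
    nucleus_diameters_um: Tuple[float, ...]
    nucleus_centers_px: Tuple[Tuple[float, float], ...]
    nucleus_body: Tuple[int, ...]  # index of the body holding each nucleus
    nucleus_halo: Tuple[bool, ...]
    agat1_positive: bool = False
    internal_membrane: bool = False

    def __post_init__(self) -> None:
        if self.nuclearity != len(self.nucleus_diameters_um):
            raise ValueError("nuclearity must equal len(nucleus_diameters_um)")
        if self.true_class == "MuN":
            if not 2 <= self.nuclearity <= 8:
                raise ValueError("MuN nuclearity must be in 2..8")
            if len(self.body_diameters_um) != 1:
                raise ValueError("MuN must have exactly one cell body")
        if self.true_class == "clump" and len(self.body_diameters_um) < 2:
            raise ValueError("clump must have at least two cell bodies")


# ---------------------------------------------------------------------------
# composition quotas
# ---------------------------------------------------------------------------

def largest_remainder_counts(n: int, probs: Sequence[float]) -> np.ndarray:
    """Integer counts summing to ``n`` proportional to ``probs`` (largest
    remainder / Hamilton apportionment; ties go to earlier entries)."""
    p = np.asarray(probs, dtype=float)
    if n < 0 or p.ndim != 1 or np.any(p < 0):
        raise ValueError("need n >= 0 and nonnegative proportions")
    total = p.sum()
    if total == 0:
        if n:
            raise ValueError("cannot allocate events to all-zero proportions")
        return np.zeros(len(p), dtype=int)
    quota = n * p / total
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _event_roster(profile: SimProfile, n_events: int, rng: np.random.Generator):
    """List of (true_class, population, nuclearity) with quota composition."""
    pops = list(profile.populations)
    labels: List[Tuple[str, Optional[str]]] = [("debris", None), ("clump", profile.clump_population)]
    probs = [profile.debris_fraction, profile.clump_fraction]
    cell_total = 1.0 - profile.debris_fraction - profile.clump_fraction
    for pop in pops:
        labels.append(("cell", pop))
        probs.append(cell_total * profile.population_mix[pop])
    counts = largest_remainder_counts(n_events, probs)

    roster: List[Tuple[str, Optional[str], int]] = []
    for (kind, pop), count in zip(labels, counts):
        if kind == "cell" and pop == profile.mun_population:
            n_mun = int(largest_remainder_counts(
                count, [profile.muns_fraction_in_E, 1.0 - profile.muns_fraction_in_E]
            )[0])
            ks = sorted(profile.nuclearity_pmf)
            k_counts = largest_remainder_counts(
                n_mun, [profile.nuclearity_pmf[k] for k in ks]
            )
            for k, kc in zip(ks, k_counts):
                roster.extend([("MuN", pop, k)] * kc)
            roster.extend([("MoN", pop, 1)] * (count - n_mun))
        elif kind == "cell":
            roster.extend([("MoN", pop, 1)] * count)
        elif kind == "clump":
            roster.extend([("clump", pop, 0)] * count)
        else:
            roster.extend([("debris", None, 0)] * count)
    order = rng.permutation(len(roster))
    return [roster[i] for i in order]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _ring_layout(k: int, body_center: np.ndarray, max_radius: float,
                 sep: float) -> Optional[np.ndarray]:
    """Deterministic fallback placement: up to 7 nuclei on a ring plus one
    in the center.  Returns None when even this layout cannot honour the
    separation."""
    if k == 1:
        return body_center[None, :]
    use_center = k >= 6
    m = k - 1 if use_center else k
    rho = max_radius
    if use_center and rho < sep:
        return None
    if 2 * rho * np.sin(np.pi / m) < sep and m > 1:
        return None
    theta = 2 * np.pi * np.arange(m) / m
    pts = body_center + rho * np.stack([np.sin(theta), np.cos(theta)], axis=1)
    if use_center:
        pts = np.vstack([body_center, pts])
    return pts


def _place_nuclei(
    rng: np.random.Generator,
    body_center: np.ndarray,
    body_radius_px: float,
    radii_px: np.ndarray,
    pad_px: float,
    max_tries: int = 200,
) -> Tuple[np.ndarray, np.ndarray]:
    """Place nucleus centers inside a cell body with pairwise separation of
    at least r_i + r_j + pad.  Rejection sampling first; on failure fall
    back to a jitter-free ring layout, shrinking radii toward the minimum
    and relaxing the pad before giving up."""
    k = len(radii_px)
    for _ in range(max_tries):
        max_r = body_radius_px - radii_px - 1.0
        if np.any(max_r <= 0):
            break
        u = rng.random(k)
        ang = rng.random(k) * 2 * np.pi
        rr = max_r * np.sqrt(u)
        pts = body_center + np.stack([rr * np.sin(ang), rr * np.cos(ang)], axis=1)
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        need = radii_px[:, None] + radii_px[None, :] + pad_px
        np.fill_diagonal(d, np.inf)
        if np.all(d >= need):
            return pts, radii_px
    r_min = float(radii_px.min())
    for radii_try in (radii_px, np.full(k, r_min)):
        for pad_try in (pad_px, 2.0, 1.0):
            sep = float(2 * radii_try.max() + pad_try)
            max_radius = body_radius_px - float(radii_try.max()) - 1.0
            pts = _ring_layout(k, body_center, max_radius, sep)
            if pts is not None:
                if k > 1:
                    # small jitter keeps galleries varied; clamp each point
                    # back inside the body so the layout stays valid
                    pts = pts + rng.normal(0.0, 0.3, size=pts.shape)
                    off = pts - body_center
                    norm = np.linalg.norm(off, axis=1, keepdims=True)
                    scale = np.minimum(1.0, max_radius / np.maximum(norm, 1e-9))
                    pts = body_center + off * scale
                return pts, radii_try
    raise PlacementError(
        f"cannot place {k} nuclei of radii {radii_px} px inside body of "
        f"radius {body_radius_px:.1f} px"
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def sample_truth(
    profile: SimProfile,
    true_class: str,
    population: Optional[str],
    nuclearity: int,
    rng: np.random.Generator,
    event_id: str,
) -> GroundTruth:
    """Draw the geometric ground truth for one event of a known class."""
    h, w = profile.raster_shape
    px = profile.pixel_size_um
    center = np.array([h / 2.0, w / 2.0]) + rng.normal(0.0, 1.5, size=2)
    lo_n, hi_n = profile.nucleus_diameter_range

    if true_class == "debris":
        d = float(rng.uniform(1.5, 3.5))
        return GroundTruth(
            event_id=event_id, true_class="debris", population=None, nuclearity=0,
            cell_diameter_um=d, body_diameters_um=(d,),
            body_centers_px=(tuple(center),), nucleus_diameters_um=(),
            nucleus_centers_px=(), nucleus_body=(), nucleus_halo=(),
        )

    if true_class == "clump":
        n_bodies = int(rng.integers(profile.clump_body_range[0],
                                    profile.clump_body_range[1] + 1))
        mean, sd = profile.clump_cell_diameter_mean_sd
        diams = [_truncated_normal(rng, mean, sd, mean - 3 * sd, mean + 3 * sd)
                 for _ in range(n_bodies)]
        radii = np.array(diams) / 2.0 / px
        ang0 = rng.uniform(0, 2 * np.pi)
        if n_bodies == 2 or rng.random() < 0.5:  # chain arrangement (elongated)
            centers = [center]
            direction = np.array([np.sin(ang0), np.cos(ang0)])
            for i in range(1, n_bodies):
                step = radii[i - 1] + radii[i] - 1.0  # 1 px overlap: connected in BF
                centers.append(centers[-1] + direction * step)
        else:  # equilateral arrangement (compact clump, survives the singlet gate)
            pair_sums = [radii[i] + radii[j]
                         for i in range(n_bodies) for j in range(i + 1, n_bodies)]
            side = float(np.mean(pair_sums)) - 1.0  # near-tangent bodies
            rho = side / np.sqrt(3.0)
            centers = [center + rho * np.array([np.sin(ang0 + 2 * np.pi * i / n_bodies),
                                                np.cos(ang0 + 2 * np.pi * i / n_bodies)])
                       for i in range(n_bodies)]
        centers = np.array(centers)
        centers -= centers.mean(axis=0) - center  # recenter the whole clump
        nuc_d, nuc_c, nuc_b, nuc_h = [], [], [], []
        for i in range(n_bodies):
            d_n = float(rng.uniform(lo_n, hi_n))
            r_n = np.array([d_n / 2.0 / px])
            pts, radii_used = _place_nuclei(rng, centers[i], radii[i], r_n,
                                            profile.min_separation_pad_px)
            nuc_d.append(float(radii_used[0] * 2 * px))
            nuc_c.append(tuple(pts[0]))
            nuc_b.append(i)
            nuc_h.append(bool(rng.random() < profile.halo_fraction))
        return GroundTruth(
            event_id=event_id, true_class="clump", population=population,
            nuclearity=n_bodies, cell_diameter_um=float(max(diams)),
            body_diameters_um=tuple(diams),
            body_centers_px=tuple(map(tuple, centers)),
            nucleus_diameters_um=tuple(nuc_d), nucleus_centers_px=tuple(nuc_c),
            nucleus_body=tuple(nuc_b), nucleus_halo=tuple(nuc_h),
            agat1_positive=bool(rng.random() < profile.agat1_positive_rate.get("other", 0.0)),
        )

    if true_class == "MuN":
        mean, sd = profile.mun_diameter_mean_sd
        d = _truncated_normal(rng, mean, sd, max(mean - 3 * sd, 13.0), mean + 3 * sd)
        body_r = d / 2.0 / px
        radii = rng.uniform(lo_n, hi_n, size=nuclearity) / 2.0 / px
        pts, radii_used = _place_nuclei(rng, center, body_r, radii,
                                        profile.min_separation_pad_px)
        halos = rng.random(nuclearity) < profile.halo_fraction
        return GroundTruth(
            event_id=event_id, true_class="MuN", population=population,
            nuclearity=nuclearity, cell_diameter_um=float(d),
            body_diameters_um=(float(d),), body_centers_px=(tuple(center),),
            nucleus_diameters_um=tuple(float(r * 2 * px) for r in radii_used),
            nucleus_centers_px=tuple(map(tuple, pts)),
            nucleus_body=tuple([0] * nuclearity),
            nucleus_halo=tuple(bool(x) for x in halos),
            agat1_positive=bool(rng.random() < profile.agat1_positive_rate.get("MuN", 0.0)),
            internal_membrane=bool(rng.random() < profile.internal_membrane_fraction),
        )

    if true_class == "MoN":
        mean, sd = profile.mon_diameter_mean_sd[population]
        d = _truncated_normal(rng, mean, sd, mean - 3 * sd, mean + 3 * sd)
        body_r = d / 2.0 / px
        r_n = np.array([rng.uniform(lo_n, hi_n) / 2.0 / px])
        pts, radii_used = _place_nuclei(rng, center, body_r, r_n,
                                        profile.min_separation_pad_px)
        return GroundTruth(
            event_id=event_id, true_class="MoN", population=population,
            nuclearity=1, cell_diameter_um=float(d), body_diameters_um=(float(d),),
            body_centers_px=(tuple(center),),
            nucleus_diameters_um=(float(radii_used[0] * 2 * px),),
            nucleus_centers_px=(tuple(pts[0]),), nucleus_body=(0,),
            nucleus_halo=(bool(rng.random() < profile.halo_fraction),),
            agat1_positive=bool(rng.random() < profile.agat1_positive_rate.get("other", 0.0)),
        )

    raise ValueError(f"unknown true_class {true_class!r}")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_GRID_CACHE: Dict[Tuple[int, int], Tuple[np.ndarray, np.ndarray]] = {}


def _grids(shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    if shape not in _GRID_CACHE:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        _GRID_CACHE[shape] = (yy.astype(float), xx.astype(float))
    return _GRID_CACHE[shape]


def _disk(shape, center, radius_px) -> np.ndarray:
    yy, xx = _grids(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px ** 2


def _annulus(shape, center, r0, r1) -> np.ndarray:
    yy, xx = _grids(shape)
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    return (d2 > r0 ** 2) & (d2 <= r1 ** 2)


def _validate_geometry(truth: GroundTruth, px: float) -> None:
    centers = np.asarray(truth.body_centers_px, dtype=float)
    for (cy, cx), d_n, body in zip(truth.nucleus_centers_px,
                                   truth.nucleus_diameters_um, truth.nucleus_body):
        bc = centers[body]
        body_r = truth.body_diameters_um[body] / 2.0 / px
        if np.hypot(cy - bc[0], cx - bc[1]) + d_n / 2.0 / px > body_r + 1e-6:
            raise PlacementError(
                f"nucleus at ({cy:.1f},{cx:.1f}) spills outside body {body} "
                f"of event {truth.event_id}"
            )


def render_event(
    truth: GroundTruth,
    profile: SimProfile,
    rng: np.random.Generator,
    stained: bool = True,
) -> EventImage:
    """Render the multi-channel raster for one ground-truth event.

    Brightfield renders bodies darker than background (absorbance-like);
    fluorescence channels render integrated intensities drawn from the
    profile's per-population log-normal models on top of a flat background,
    with the Draq5 total scaling linearly in nuclearity.  When ``stained``
    is false only backgrounds and noise are rendered (unstained control).
    """
    _validate_geometry(truth, profile.pixel_size_um)
    shape = profile.raster_shape
    px = profile.pixel_size_um
    noise = profile.noise
    channels = profile.channels
    pop = truth.population

    body_masks = [
        _disk(shape, np.asarray(c), d / 2.0 / px)
        for c, d in zip(truth.body_centers_px, truth.body_diameters_um)
    ]
    union = np.logical_or.reduce(body_masks) if body_masks else np.zeros(shape, bool)

    pages: Dict[str, np.ndarray] = {}

    # --- brightfield: dark absorbing object on a bright background; each
    # body's boundary rim absorbs extra, so cell-cell contact interfaces in
    # clumps show as dark seams (the cue that separates clumps from MuNs)
    bf = np.full(shape, noise.bf_background, dtype=float)
    bf -= noise.bf_cell_depth * union
    if noise.bf_rim_depth:
        for c, d in zip(truth.body_centers_px, truth.body_diameters_um):
            r = d / 2.0 / px
            rim = _annulus(shape, np.asarray(c), max(r - noise.bf_rim_width_px, 0.0), r)
            bf -= noise.bf_rim_depth * rim
    pages["BF"] = bf

    # --- Calcein: cytoplasm of viable bodies ------------------------------
    if "Calcein" in channels:
        cal = np.zeros(shape, dtype=float)
        if stained and truth.true_class != "debris":
            loc, scale = profile.intensity.calcein_log10[pop]
            for mask in body_masks:
                area = int(mask.sum())
                if area:
                    total = 10.0 ** rng.normal(loc, scale)
                    cal[mask] += total / area
        pages["Calcein"] = cal

    # --- Draq5: near-circular nuclear blobs, optional dim halo ring -------
    if "Draq5" in channels:
        draq = np.zeros(shape, dtype=float)
        if stained and truth.nuclearity:
            loc, scale = profile.intensity.draq5_log10[pop]
            # one per-nucleus base intensity per body: total scales with nuclearity
            base_by_body = {b: 10.0 ** rng.normal(loc, scale)
                            for b in set(truth.nucleus_body)}
            for (cy, cx), d_n, body, halo in zip(
                truth.nucleus_centers_px, truth.nucleus_diameters_um,
                truth.nucleus_body, truth.nucleus_halo,
            ):
                r_n = d_n / 2.0 / px
                blob = _disk(shape, (cy, cx), r_n)
                area = max(int(blob.sum()), 1)
                amp = base_by_body[body] / area
                draq[blob] += amp
                if halo:
                    ring = _annulus(shape, (cy, cx), r_n, r_n + profile.halo_width_px)
                    draq[ring] += profile.halo_relative_intensity * amp
        pages["Draq5"] = draq

    # --- CellBrite: plasma-membrane ring, plus internal membranes ---------
    if "CellBrite" in channels:
        cb = np.zeros(shape, dtype=float)
        if stained and truth.true_class != "debris":
            loc, scale = profile.intensity.cellbrite_log10
            for c, d in zip(truth.body_centers_px, truth.body_diameters_um):
                r = d / 2.0 / px
                ring = _annulus(shape, np.asarray(c), r - 1.0, r + 0.5)
                n_ring = max(int(ring.sum()), 1)
                cb[ring] += 10.0 ** rng.normal(loc, scale) / n_ring
            if truth.true_class == "MuN" and truth.internal_membrane and truth.nuclearity >= 2:
                # ridges of the nearest-nucleus partition inside the body
                yy, xx = _grids(shape)
                pts = np.asarray(truth.nucleus_centers_px)
                d2 = (yy[None] - pts[:, 0, None, None]) ** 2 + (xx[None] - pts[:, 1, None, None]) ** 2
                lab = np.argmin(d2, axis=0)
                edge = np.zeros(shape, bool)
                edge[:-1, :] |= lab[:-1, :] != lab[1:, :]
                edge[:, :-1] |= lab[:, :-1] != lab[:, 1:]
                edge &= union
                if edge.any():
                    cb[edge] += cb[cb > 0].mean() if (cb > 0).any() else 10.0
        pages["CellBrite"] = cb

    # --- AGAT-1 antibody ---------------------------------------------------
    if "AGAT1" in channels:
        ag = np.zeros(shape, dtype=float)
        if stained and truth.true_class != "debris" and union.any():
            loc, scale = (profile.intensity.agat1_positive_log10 if truth.agat1_positive
                          else profile.intensity.agat1_negative_log10)
            ag[union] += 10.0 ** rng.normal(loc, scale) / int(union.sum())
        pages["AGAT1"] = ag

    stack = []
    channel_map = {}
    for i, role in enumerate(channels):
        img = ndimage.gaussian_filter(pages[role], noise.blur_sigma_px)
        if role != "BF":
            img = img + noise.fluor_background
            if noise.shot_noise:
                img = img + rng.standard_normal(shape) * np.sqrt(np.clip(img, 0, None))
        if noise.read_noise_sd > 0:
            img = img + rng.normal(0.0, noise.read_noise_sd, size=shape)
        stack.append(np.clip(img, 0.0, None).astype(np.float32))
        channel_map[role] = i

    return EventImage(
        pixels=np.stack(stack), channel_map=channel_map,
        pixel_size_um=px, event_id=truth.event_id,
    )


# ---------------------------------------------------------------------------
# cohort-level drivers
# ---------------------------------------------------------------------------

def simulate_events(
    profile: SimProfile,
    n_events: int,
    seed: Optional[int] = None,
    stained: bool = True,
) -> Iterator[Tuple[GroundTruth, EventImage]]:
    """Yield ``n_events`` (ground truth, image) pairs, reproducibly."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    seed = profile.seed if seed is None else int(seed)
    ss = np.random.SeedSequence(seed)
    roster_rng = np.random.default_rng(ss.spawn(1)[0])
    roster = _event_roster(profile, n_events, roster_rng)
    children = ss.spawn(n_events)
    for i, ((cls, pop, k), child) in enumerate(zip(roster, children)):
        rng = np.random.default_rng(child)
        truth = sample_truth(profile, cls, pop, k, rng, event_id=f"ev{i:06d}")
        yield truth, render_event(truth, profile, rng, stained=stained)


def truth_table(truths: Sequence[GroundTruth]) -> pd.DataFrame:
    """Flatten ground-truth records into a table (one row per event)."""
    rows = []
    for t in truths:
        rows.append({
            "event_id": t.event_id,
            "true_class": t.true_class,
            "true_population": t.population,
            "true_nuclearity": t.nuclearity,
            "true_cell_diameter_um": t.cell_diameter_um,
            "true_n_bodies": len(t.body_diameters_um),
            "true_nucleus_diameters_um": ";".join(
                f"{d:.4f}" for d in t.nucleus_diameters_um),
            "true_agat1_positive": t.agat1_positive,
        })
    return pd.DataFrame(rows)


def simulate_cohort(
    profile: SimProfile,
    n_events: int,
    out_dir: str | Path,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Write a cohort to disk (events/*.tif + ground_truth.csv + manifest)
    and return the ground-truth table."""
    from . import io as mio  # local import: tifffile only needed on this path

    out = Path(out_dir)
    events_dir = out / "events"
    events_dir.mkdir(parents=True, exist_ok=True)
    truths: List[GroundTruth] = []
    files: List[str] = []
    for truth, image in simulate_events(profile, n_events, seed=seed):
        path = events_dir / f"{truth.event_id}.tif"
        mio.write_event_tiff(path, image)
        truths.append(truth)
        files.append(str(path.relative_to(out)))
    table = truth_table(truths)
    table.to_csv(out / "ground_truth.csv", index=False)
    profile_json = profile.model_dump_json()
    manifest = {
        "profile": json.loads(profile_json),
        "profile_sha256": hashlib.sha256(profile_json.encode()).hexdigest(),
        "seed": profile.seed if seed is None else int(seed),
        "n_events": n_events,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return table


def simulate_unstained_control(
    profile: SimProfile,
    n_events: int,
    seed: Optional[int] = None,
    morph_params=None,
) -> pd.DataFrame:
    """Event-feature table of an unstained control sample.

    The same cells are rendered but fluorescence signal is withheld, so the
    measured channel intensities are pure background; their upper quantiles
    calibrate the positivity thresholds.
    """
    from .morphometry import MorphometryParams, features_table

    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    params = morph_params or MorphometryParams()
    seed = (profile.seed + 0x5A11) if seed is None else int(seed)
    pairs = simulate_events(profile, n_events, seed=seed, stained=False)
    return features_table((img for _, img in pairs), params)


def simulate_intensity_table(
    profile: SimProfile,
    n_events: int,
    seed: Optional[int] = None,
    unstained: bool = False,
) -> pd.DataFrame:
    """Sorter-style event table: intensities drawn directly from the
    profile's models plus area/aspect scatter proxies, no images.

    Mirrors the conventional-cytometer workflow where only integrated
    intensities are recorded.  Ground-truth columns (`true_*`) ride along
    for recovery scoring.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    seed = profile.seed if seed is None else int(seed)
    ss = np.random.SeedSequence([seed, 0xFAC5])
    rng = np.random.default_rng(ss)
    roster = _event_roster(profile, n_events, rng)
    rows = []
    for i, (cls, pop, k) in enumerate(roster):
        row: Dict[str, object] = {
            "event_id": f"ev{i:06d}", "true_class": cls,
            "true_population": pop, "true_nuclearity": k,
        }
        if cls == "debris":
            cal = rng.normal(0.0, 30.0)
            draq = rng.normal(0.0, 30.0)
            area = np.pi * rng.uniform(1.5, 3.5) ** 2 / 4.0
            aspect = rng.uniform(0.3, 1.0)
            agat = rng.normal(0.0, 30.0)
            agat_pos = False
        else:
            c_loc, c_scale = profile.intensity.calcein_log10[pop]
            d_loc, d_scale = profile.intensity.draq5_log10[pop]
            if cls == "clump":
                n_bodies = int(rng.integers(profile.clump_body_range[0],
                                            profile.clump_body_range[1] + 1))
                cal = sum(10.0 ** rng.normal(c_loc, c_scale) for _ in range(n_bodies))
                draq = sum(10.0 ** rng.normal(d_loc, d_scale) for _ in range(n_bodies))
                mean, sd = profile.clump_cell_diameter_mean_sd
                area = n_bodies * np.pi * rng.normal(mean, sd) ** 2 / 4.0
                aspect = (rng.uniform(0.30, 0.55) if n_bodies == 2 or rng.random() < 0.5
                          else rng.uniform(0.70, 0.90))
                row["true_nuclearity"] = n_bodies
            else:
                cal = 10.0 ** rng.normal(c_loc, c_scale)
                draq = max(k, 1) * 10.0 ** rng.normal(d_loc, d_scale)
                if cls == "MuN":
                    mean, sd = profile.mun_diameter_mean_sd
                else:
                    mean, sd = profile.mon_diameter_mean_sd[pop]
                area = np.pi * _truncated_normal(rng, mean, sd, mean - 3 * sd,
                                                 mean + 3 * sd) ** 2 / 4.0
                aspect = rng.uniform(0.75, 1.0)
            rate_key = "MuN" if cls == "MuN" else "other"
            agat_pos = bool(rng.random() < profile.agat1_positive_rate.get(rate_key, 0.0))
            a_loc, a_scale = (profile.intensity.agat1_positive_log10 if agat_pos
                              else profile.intensity.agat1_negative_log10)
            agat = 10.0 ** rng.normal(a_loc, a_scale)
        if unstained:
            cal = rng.normal(0.0, 30.0)
            draq = rng.normal(0.0, 30.0)
            agat = rng.normal(0.0, 30.0)
        row.update({
            "calcein_intensity": float(cal),
            "draq5_intensity": float(draq),
            "agat1_intensity": float(agat),
            "cell_area": float(area),
            "aspect_ratio": float(np.clip(aspect, 0.0, 1.0)),
            "true_agat1_positive": agat_pos,
        })
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR plate simulation
# ---------------------------------------------------------------------------

class QpcrDesign(BaseModel):
    """True relative-expression design for a simulated qPCR experiment.

    ``fold_changes[condition][gene]`` is the true expression of *gene* in
    *condition* relative to ``control_condition``; a fold change f is
    encoded as a dCt shift of -log2(f), so the ddCt analysis inverts it
    exactly at zero noise.
    """

    reference_gene: str = "Ef2"
    control_condition: str = "WT"
    base_ct: Dict[str, float]
    reference_ct: float = 18.0
    fold_changes: Dict[str, Dict[str, float]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "QpcrDesign":
        for cond, genes in self.fold_changes.items():
            for gene, f in genes.items():
                if f <= 0:
                    raise ValueError(
                        f"fold change for {gene!r} in {cond!r} must be > 0, got {f}")
                if gene not in self.base_ct:
                    raise ValueError(f"fold change for unknown gene {gene!r}")
        return self

    @property
    def conditions(self) -> Tuple[str, ...]:
        return (self.control_condition, *self.fold_changes.keys())


def simulate_ct_table(
    design: QpcrDesign,
    reps: int = 3,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format Ct table: (sample, condition, gene, replicate, ct).

    Technical replicates are the true Ct plus Gaussian cycle noise
    (default sd 0.15 cycles).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC7]))
    rows = []
    for cond in design.conditions:
        folds = design.fold_changes.get(cond, {})
        genes = {design.reference_gene: design.reference_ct, **design.base_ct}
        for gene, base in genes.items():
            true_ct = base
            if gene != design.reference_gene:
                true_ct = base - np.log2(folds.get(gene, 1.0))
            for rep in range(1, reps + 1):
                ct = true_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append({
                    "sample": cond, "condition": cond, "gene": gene,
                    "replicate": rep, "ct": float(ct),
                })
    return pd.DataFrame(rows)
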