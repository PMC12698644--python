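# Methods

## What the generator emulates

Each simulated acquisition event is a 64×64 px, 0.5 µm/px multi-channel
raster (configurable): brightfield (BF), Calcein (cytoplasm of viable
cells), Draq5 (nuclei), and optionally CellBrite (membrane) and AGAT-1
(antibody). A `SimProfile` fixes one acquisition condition:

- **Composition.** Events are debris (default 5%), MoN clumps (3%), or
  single cells split over the intensity-plane populations. The wild-type
  image-stream mix uses the published double-positive shares — D′ 16%,
  E′ 54.8% — with the unprinted remainder split evenly between B′ and C′
  (14.6% each). The histone-H2B knockdown mix is D′ 3.1%, E′ 34%. MuNs live
  in population E′ at 2% of E′ events in wild type, which puts them at
  ~1.1% of all double positives; the knockdown profiles scale that share to
  0.8× (H2B) and 0.4× (Agat-1) of the wild-type level, the Agat-1 profile
  leaving the population mix unchanged. Sorter-style (A–E) profiles encode
  E 25.3%/D 14.7% (wild type) and E 9.1%/D 9.0% (H2B knockdown).
- **Geometry.** MuN cell diameters are N(16, 1) µm (truncated at 13 µm so
  eight nuclei always fit); MoN diameters are population-specific normals
  spanning 8–10 µm; nuclei are uniform 3–4 µm everywhere, reflecting that
  nuclear size does not vary with nuclearity. The nuclearity distribution
  puts 0.67 on two nuclei and spreads 0.33 over 3–8 with geometric decay
  (ratio 0.5) — only the 2-versus->2 split and the 3–8 range are
  constrained; the decay is a modeling choice. Clumps are 2–3 mononucleated
  cells, arranged either in a near-tangent chain or an equilateral compact
  cluster (half of 3-cell clumps), each overlapping its neighbour by ~1 px
  so the union is connected in brightfield.
- **Intensities.** Integrated per-event intensities are log10-normal per
  population (scale 0.1 dex); a cell's total Draq5 signal is its per-nucleus
  draw times its nuclearity, which is what places MuNs at the top of the
  double-positive intensity range. Rendered per-pixel amplitude is the
  integrated draw divided by the object's pixel area.
- **Optics.** All channels share a Gaussian point-spread surrogate
  (σ = 0.7 px). Brightfield renders bodies as absorbance (depth 80 on a
  background of 200) plus an extra-dark 1.5 px rim inside each body's
  boundary — in clumps these rims form the dark contact seams a reviewer
  uses to tell a clump from a MuN. Fluorescence channels add a flat
  background (5), Poisson-like shot noise and Gaussian read noise
  (σ = 2). A configurable fraction of nuclei (default 0.3) carries a halo
  ring at 25% of the nuclear amplitude. "Noiseless" renders keep the blur
  and backgrounds but silence both noise sources.
- **Sampling design.** Per-cohort class, population and nuclearity counts
  are allocated by largest-remainder proportional quota and shuffled (the
  convention scikit-learn's synthetic generators use), rather than drawn
  iid. Recovery experiments then measure detection error, not sampling
  error; empirical frequencies match profile probabilities to within one
  count. Per-event attributes (sizes, positions, intensities, noise) remain
  random, with one child RNG stream per event spawned from the cohort seed,
  so cohorts are bitwise reproducible and any event can be re-rendered in
  isolation.

What the generator does **not** emulate: realistic PSF/optics, 3-D
structure, spectral spillover, sorter physics, autofocus failures, or the
full morphological heterogeneity of dissociated tissue. Cells are discs and
nuclei are circular blobs. Passing tests therefore demonstrate that the
analysis chain is correct and well-calibrated under its stated model — not
that it would meet the same accuracy on instrument data.

## Measurement chain

**Background.** Per channel, background level and noise are the median and
MAD of the frame border.

**Cell mask.** The BF darkness (background − BF) is smoothed (σ = 1 px) and
thresholded at max(Otsu, 3× border noise); the mask is closed (radius 2),
hole-filled, reduced to its largest connected component, and optionally
eroded. `erode_radius` defaults to 0: the synthetic brightfield edge is a
symmetric blur, so the threshold boundary is already unbiased; the knob
exists for data whose raw BF mask overshoots. Equivalent-circle diameter
2·√(area/π) is the size readout.

**Nuclear mask chain** (the LevelSet/Watershed/Component surrogate):
smooth Draq5, threshold inside the 2 px-dilated cell mask at max(Otsu over
that region, 3× noise); within each candidate component, discard pixels
below 0.30× the component peak (halo rejection — rendered halos sit at
0.25×); split touching spots by watershed on the Euclidean distance
transform, seeded at h-maxima (h = 1) with seeds closer than 3 px merged;
absorb regions smaller than a 1.5 µm circle into their largest touching
neighbour; rank surviving components by area (ties: top-left centroid) and
keep at most `component_cap` = 8, setting an overflow flag beyond the cap.
Nucleus diameters are reported zero-padded to the cap.

**Calcein bodies.** For clump separation, the calcein mask (threshold: half
the median within-cell level — an Otsu split inside the cell mask would
separate bright from dim bodies, not signal from background) is cut
wherever BF darkness exceeds 1.25× its within-cell median (the contact
seams), then split by the same distance-transform watershed with a minimum
body size of a 4 µm circle. Sub-minimum attachments (anucleate debris) are
not counted as bodies.

**Gating.** Positivity thresholds are the 99.5th percentile of an unstained
control's measured intensities. The image-stream hierarchy is focus
(gradient RMS ≥ 2) → debris removal (area ≥ 12.5 µm²) → singlet
(aspect ratio ≥ 0.6) → Calcein⁺ → Draq5⁺ → population rectangles on
(log10 Calcein, log10 Draq5). The default rectangles are quadrants at
(4.05, 3.95), midway between the low/high staining modes of the default
intensity model after mask losses; `fit_population_gates` refits them from
any labelled cohort. Rectangles are half-open, so populations partition the
double-positive pool exactly. The singlet gate is shape-based only: an
upper area cut is available as config but off by default, because MuNs are
legitimately the largest ~1% of events and an unconditional upper-quantile
area cut would remove them — the E1 experiment (`skip_singlet`) exists
precisely to verify MuNs are not lost to doublet discrimination.

**Classification.** In order: no nuclei → unresolved; ≥2 calcein bodies
each containing a nucleus → clump; ≥2 nuclei in one body with solidity
≥ 0.85 and no overflow → MuN; remaining ≥2-nuclei events → clump; one
nucleus → MoN. Deterministic given features.

**Statistics.** Replicate metrics are summarized by medians (headline) and
means; knockdown ratios divide condition medians by the control median.
ANOVA/Tukey are assembled from scipy's F and studentized-range
distributions so zero-variance groups take explicit degenerate paths
(infinite statistic, p = 0 for separated means; p = 1 for identical ones)
instead of NaN. The t-test defaults to pooled variance (smallest assumption
set at n = 3), Welch via config. Holm–Bonferroni is applied across each
reported pairwise family. The regeneration-stability check simulates
replicate MuN proportions from the binomial measurement model at the
pipeline's double-positive depth; running the full image pipeline for
hundreds of repetitions would measure the same thing at far higher cost.

**qPCR.** Amplification efficiency is fixed at 2 and technical replicates
are averaged on the Ct scale before the exponent (canonical Livak
procedure), so log2(fold change) = −ΔΔCt exactly and the zero-noise round
trip with the plate simulator is exact.

## Numerical and design notes

- All intensities are arbitrary units; only relative positions in log10
  space matter, and the gate geometry is config.
- Component ranking ties break on (row, column) of the centroid for
  deterministic label order.
- Nucleus placement uses rejection sampling with pairwise separation
  ≥ r_i + r_j + 4 px; on failure it falls back to a deterministic ring
  layout, shrinking nuclei toward the 3 µm minimum and then relaxing the
  pad before raising a placement error. High-nuclearity events in small
  cells may therefore carry slightly smaller nuclei.
- The problem sizes used by the test suite and the acceptance script
  (10,000-event reference cohort; 3×5,000-event knockdown replicates;
  hundreds of events for property checks) were chosen so quota-level
  composition error is negligible against the published precision.
- Known limitations: the classifier does not use the membrane channel (the
  cue for fusion-stage morphology is rendered but deliberately unused);
  no nuclear-envelope modeling; aspect-ratio doublet discrimination removes
  chain clumps but passes compact equilateral ones by design, leaving their
  rejection to the multi-body rule.
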