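# Methods

This note documents the models, parameters and numerical choices behind
`printarray`, and what the synthetic-data generator does and does not
emulate.

## The system being modelled

A printed community is a 2D lattice of ~110-µm agarose droplets, each
seeded from a bioink at ~10⁸ cells mL⁻¹ (≈70 founder cells per
droplet).  Over ~18 h each founder grows into a clonal 3D microcolony
of median diameter ~15 µm; starting centre-to-centre distances are
~18 µm.  Two genotypes carry distinct fluorophores, so a two-channel
confocal image separates them.  Analysis proceeds: z-projection →
microcolony segmentation → print isolation/registration → per-pixel
genotype masks → segregation index SI(h) → outcome metrics.

## Synthetic scenes (`synthgen`)

The generator defines the study conditions; its defaults are fixed:

| parameter | default | meaning |
|---|---|---|
| droplet diameter | 110 µm | printed droplet size |
| lattice pitch | 110 µm | tangent disks on a square lattice |
| cell density | 10⁸ mL⁻¹ | Poisson mean 69.7 cells per droplet |
| colony median diameter | 15 µm | log-normal population median |
| colony log-sigma | 0.55 | gives quartiles ≈ 10–21 µm |
| pixel size | 1.515 µm | 100 px span ↔ 151.5 µm |
| z-step | 2.73 µm | confocal stack spacing |
| canvas margin | 2 droplet diameters | room for debris and rotation |
| background / noise / amplitude | 10 / 2 / 100 | imaging model |

Founder counts are Poisson with mean `density × (4/3)π(d/2)³`
(deterministic counts are available for exact-count tests); positions
are uniform over the droplet footprint; MIXED droplets assign genotypes
per cell Bernoulli(mix_fraction).  Colony diameters are log-normal —
positive support and asymmetric quartiles match the reported size
distribution; log-sigma 0.55 reproduces the 10–21 µm interquartile
range around a 15-µm median.  The imaging model is additive: disk
(2D) / sphere (3D) intensity profiles with a soft 1-px edge, each
colony emitting only in its genotype's channel, plus a constant
background, optional linear gradient, and Gaussian noise.  A single
integer seed drives a hierarchical `SeedSequence` (cells → sizes →
debris → noise), so scenes are bit-reproducible and sub-streams are
independent.

What the generator does **not** emulate: growth competition (imposed
patterns only — no colicin killing, autoinduction or nutrient
dynamics), optical blur/PSF, bleed-through between channels,
droplet-packing physics, or z-dependent attenuation.  Passing tests
therefore demonstrate the correctness of the measurement chain on
idealised imagery, not robustness to every artefact of real
micrographs.

Reference masks render each droplet as a filled disk of per-pixel
genotype labels; MIXED droplets are per-pixel Bernoulli fields.  These
are idealisations: a real (or simulated) mixed print is clonal at the
microcolony scale, so at spans comparable to a colony diameter its
measured SI greatly exceeds the reference's ≈0.5.  Comparisons against
reference masks are therefore meaningful at spans well above the colony
size (the headline 100-µm/100-px scale); even there a small
clonal-granularity excess of ~0.01–0.03 remains in mixed scenes.

## 2D segmentation (`segment2d`)

Pipeline: Gaussian smoothing of the channel-sum image (σ = 2 px);
foreground by Otsu threshold on the smoothed sum; dark inter-colony
ridges (pixels whose largest 2D Hessian eigenvalue at the 3-px gap
scale is positive and above the 75th percentile of positive values)
subtracted from the foreground; watershed flooded from regional maxima
with a minimum prominence of 10% of the dynamic range; components
below 10 px² dropped.  All parameters sit in `Segment2DParams` and are
scale-matched to 15-µm colonies at 1.515 µm/px.  Whether to threshold
each channel separately or the combined image is an open choice; the
channel-sum is used so that segmentation is genotype-agnostic.
Watershed and relabelling are deterministic (scan-order), so label
masks are reproducible byte-for-byte.

Features come from the label mask: unweighted pixel centroids (µm,
origin at the top-left pixel centre), equivalent-ellipse axes from
second central moments, and orientation measured from the +x axis,
counter-clockwise positive with y up, in [−90°, 90°).

## 3D segmentation (`segment3d`)

A rough mask (`I > level`, Otsu by default) is refined by removing dark
separating features.  The stack is smoothed with a Gaussian of physical
scale σ (default 3 µm ≈ the inter-colony gap), specified in µm and
converted per-axis to voxels so the filter is isotropic despite the
1.515 µm xy / 2.73 µm z anisotropy.  Second derivatives are taken by
Gaussian-derivative convolution (not finite differences) and expressed
per µm²; the 3×3 Hessian is diagonalised per voxel and eigenvalues are
ordered |λ1| ≥ |λ2| ≥ |λ3|.  A locally dark blob/sheet/tube has λ1
strongly positive, so the separator mask is `λ1 > τ` with λ1 compared
*signed* — bright colony interiors (λ1 ≪ 0) are never flagged.

The final mask keeps rough-mask voxels that are **not** separators
(`rough AND NOT separator`).  Reading the refinement as a literal
intersection with the separator set would keep only the dark seams and
discard the colonies, defeating the stated purpose of splitting
closely packed colonies; the literal combination remains selectable
(`combine="literal"`) for comparison.  Components are labelled with
26-connectivity.

The default curvature threshold is `τ = 0.1 × p99(|λ1|)` — a
noise-margin fraction of the stack's characteristic curvature scale.
A percentile of the *positive* λ1 population was considered and
rejected: in well-segmented data that population is dominated by the
separator voxels themselves plus the bright/background shell, so a
high percentile discards most of the separator plane and touching
colonies fail to split.  Percentile (`"p90"`) and absolute thresholds
remain available.

## Print geometry (`printgeom`)

*Centre and size.*  The centre is the mean colony position; with r̄ the
mean radial distance, the side of an assumed-square print is
`L = r̄ / 0.382598...` where the constant is E(r)/L for a uniform point
in a square, `(√2 + ln(1+√2))/6`.

*Isolation.*  Colonies beyond `margin_factor × L√2/2` (the
half-diagonal with 15% slack, `margin_factor = 1.15`) are removed; the
centre is recomputed and the threshold re-applied once.  The slack
accepts the print's own corners while rejecting distant debris.

*Registration.*  The convex hull's boundary distance from the centre is
resampled onto N = 360 regular polar angles by exact ray–polygon
intersection — hull *vertices* cluster at the corners, and
interpolating their distances alone distorts the profile enough to
cost several degrees of accuracy.  After mean subtraction, the print
rotation is the phase of the DFT at wavenumber 4 (a square's corners
make d(φ) 4-periodic): θ = (1/4)(π − arg Σ d(φₙ)e^(−i8πn/N)), reported
in [−45°, 45°); registration rotates all centroids by −θ.  The sign
convention is internal; correctness is established by recovery tests
(|θ̂ − θ| mod 90° < 1° over 100 random rotations).

*Neighbours.*  Delaunay edges define neighbour pairs.  Colonies
"forming the outer boundary" are flagged as hull vertices **plus** any
colony within 1% of the mean hull radius of the hull polygon:
near-collinear boundary colonies are not Qhull vertices, yet their
edges carry triangulation boundary artefacts (e.g. spurious
next-next-row edges along a lattice edge).  Edges touching any
boundary colony are excluded from the reported distance distribution.
On near-degenerate square grids the triangulation's diagonal choice is
tie-broken by jitter; tests accept either diagonal.

## Segregation index (`segregation`)

Genotype assignment thresholds each channel separately with Otsu's
method and labels a pixel A/B only when exactly one channel exceeds its
threshold; both-above *and* both-below pixels carry no genotype
(background has no genotype; only genotype-bearing pixels are ever
counted).  Otsu runs on log(1 + I) by default: projected fluorescence
is heavy-tailed where colonies overlap, and on linear intensities the
two channels' thresholds can land in different histogram modes,
skewing SI by up to ~0.2 on mixed scenes; the log transform removes
this failure mode.  Linear-scale Otsu and explicit raw-intensity
thresholds remain available.  Constant channels are an error unless
explicit thresholds are given.

`s_i(h)` uses the (2h+1)×(2h+1) square window clipped at borders, with
the focal pixel included in its own neighbour count (this keeps
N_i ≥ 1 so s_i is defined everywhere; an exclude-self variant is a
flag, and the headline quantities are insensitive at h ≥ 20 px).  The
implementation uses summed-area tables — O(1) per pixel per span — and
is held to *exact* agreement with a direct double-loop oracle on
64×64 masks in the tests.  A span of S µm means h = round(S /
pixel_size) px; at the calibrated 1.515 µm/px, spans of 5, 10, 20, 50,
100 px correspond to 7.6–151.5 µm and the headline 100-µm neighbourhood
is h = 66 px.

On the idealised 7×8 segregated-halves reference this yields
SI(100 µm) ≈ 0.94 (one mixed band of width 2h around the single
interface, mean s ≈ 3/4, against an 880-µm extent), and per-pixel 1:1
mixed references yield ≈ 0.50.

## Outcome metrics (`ecolmetrics`)

Frequency `f = A_a/(A_a + A_b)` and productivity `p = A_a/A_S` accept
any consistent abundance basis (area µm², volume µm³, cells, CFU).
`A_S` must come from a matched no-interference control and is always
supplied explicitly — the pipeline never infers it.  Flow gating keeps
the central 90% of events per scatter axis (an axis-aligned
quantile box — the "core of the population" is otherwise unspecified;
a box is simple and deterministic), splits genotypes at a fluorescence
of 2^9.5 ≈ 724, and counts the first 3000 gated events in acquisition
order (fewer triggers a warning and uses all).  Doubling time is
ln 2 / slope of a least-squares fit of ln OD against time over the
OD 0.2–0.7 exponential window; a slope ≤ 10⁻¹² (flat/declining) is an
error.  Lag-phase estimation is out of scope.

## Pipeline

`run_pipeline` executes simulate → segment2d → geometry → SI → metrics
from a single YAML-serialisable config, writing per-stage TIFF/CSV/JSON
outputs plus a manifest (config hash, seed, library versions).  Stage
failures abort with the stage named; outputs already written are kept.
Frequencies are computed on the genotype-mask area basis, mirroring how
cross-sectional areas are obtained from projected images.

## Problem sizes and test scope

Tests run at desk scale: 7×8 prints (≈4000 colonies, ≈870×800 px
images), 3D stacks of ≈20×40×60 voxels, 1000-point geometry fixtures
with 50–100 seeds, and 64×64 SI oracle masks.  The 0.65 area-ratio
recovery uses a 7×20 strip print so the imposed ratio is exactly 13/20.
These sizes were chosen to exercise every code path with comfortable
statistical margins.

## Known limitations

* The 2D watershed is tuned for convex, roughly isotropic
  microcolonies; filamentous growth would need different markers.
* The side-length estimator assumes square prints; rectangles are
  handled only through the registered extent.
* No PSF/blur model in the generator, so segmentation accuracy on real
  confocal data will be somewhat lower than the synthetic benchmarks.
* SI is 2D only (squares, not circles, by construction) and reference
  comparisons are meaningful only at spans above the colony scale.
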