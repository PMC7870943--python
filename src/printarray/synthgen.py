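"""Synthetic printed-array scenes with ground truth.

Emulates droplet-printed bacterial communities: a small lattice of
~110-µm agarose droplets, each seeded with tens of founder cells that
grow into fluorescent microcolonies (median diameter ~15 µm).  The
generator produces the designed genotype layout (the printing map), the
idealised reference rendering used to score printing fidelity, and
realistic two-channel micrographs / confocal stacks with per-colony
ground truth, so every downstream analysis stage can be tested without
any experimental imagery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Defaults: the study conditions the generator emulates
# ---------------------------------------------------------------------------

#: µm per pixel of the confocal projections (100 px span = 151.5 µm).
DEFAULT_PIXEL_SIZE = 1.515
#: confocal z-step, µm.
DEFAULT_Z_STEP = 2.73
#: droplet diameter, µm.
DEFAULT_DROPLET_DIAMETER = 110.0
#: bioink cell density, cells per mL; ~70 cells in a 110-µm droplet.
DEFAULT_CELL_DENSITY = 1e8
#: median microcolony diameter after growth, µm.
DEFAULT_COLONY_MEDIAN_DIAMETER = 15.0
#: log-sigma of the colony diameter log-normal; quartiles ~ (10, 21) µm
#: around a 15-µm median.
DEFAULT_COLONY_LOG_SIGMA = 0.55
#: background margin around the print, in droplet diameters.
CANVAS_MARGIN_DROPLETS = 2.0

#: genotype mask codes shared with :mod:`printarray.segregation`.
NONE, A, B = 0, 1, 2

_LABELS = ("A", "B", "EMPTY", "MIXED")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PrintingMap:
    """Designed per-droplet genotype layout plus droplet geometry.

    ``assignment`` is an ``(n_y, n_x)`` array of strings from
    ``{"A", "B", "EMPTY", "MIXED"}``; ``mix_fraction`` is the proportion
    of genotype A inside MIXED droplets.
    """

    n_x: int
    n_y: int
    assignment: np.ndarray
    droplet_diameter: float = DEFAULT_DROPLET_DIAMETER
    pitch: float = DEFAULT_DROPLET_DIAMETER
    mix_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=object)
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("map must have at least one droplet per axis")
        if self.assignment.shape != (self.n_y, self.n_x):
            raise ValueError(
                f"assignment shape {self.assignment.shape} does not match "
                f"(n_y, n_x) = ({self.n_y}, {self.n_x})"
            )
        bad = set(np.unique(self.assignment.astype(str))) - set(_LABELS)
        if bad:
            raise ValueError(f"unknown droplet labels: {sorted(bad)}")
        if self.droplet_diameter <= 0:
            raise ValueError("droplet_diameter must be positive")
        if self.pitch < 0:
            raise ValueError("pitch must be non-negative")
        if not 0.0 <= self.mix_fraction <= 1.0:
            raise ValueError("mix_fraction must lie in [0, 1]")

    def droplet_centres(self) -> np.ndarray:
        """Centres of all droplets, µm, shape ``(n_y*n_x, 2)`` as (x, y)."""
        jj, ii = np.meshgrid(np.arange(self.n_x), np.arange(self.n_y))
        x = (jj.ravel() + 0.5) * self.pitch
        y = (ii.ravel() + 0.5) * self.pitch
        return np.column_stack([x, y])

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the print footprint, µm."""
        return self.n_x * self.pitch, self.n_y * self.pitch

    # -- serialisation ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_x": self.n_x,
            "n_y": self.n_y,
            "droplet_diameter": self.droplet_diameter,
            "pitch": self.pitch,
            "mix_fraction": self.mix_fraction,
            "assignment": self.assignment.astype(str).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PrintingMap":
        d = json.loads(Path(path).read_text())
        return cls(
            n_x=d["n_x"],
            n_y=d["n_y"],
            assignment=np.array(d["assignment"], dtype=object),
            droplet_diameter=d.get("droplet_diameter", DEFAULT_DROPLET_DIAMETER),
            pitch=d.get("pitch", DEFAULT_DROPLET_DIAMETER),
            mix_fraction=d.get("mix_fraction", 0.5),
        )

    def to_csv(self, path: str | Path) -> None:
        """Grid-of-labels CSV dialect (one row per droplet row)."""
        pd.DataFrame(self.assignment.astype(str)).to_csv(
            path, header=False, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, **geometry) -> "PrintingMap":
        grid = pd.read_csv(path, header=None, dtype=str).to_numpy(dtype=object)
        return cls(n_x=grid.shape[1], n_y=grid.shape[0], assignment=grid, **geometry)


@dataclass
class Micrograph:
    """Two-channel 2D fluorescence image with physical pixel size (µm)."""

    channels: tuple[np.ndarray, np.ndarray]
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        c1, c2 = (np.asarray(c, dtype=float) for c in self.channels)
        if c1.shape != c2.shape:
            raise ValueError("channels must share a shape")
        if c1.ndim != 2:
            raise ValueError("channels must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.channels = (c1, c2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    def channel_sum(self) -> np.ndarray:
        return self.channels[0] + self.channels[1]


@dataclass
class VoxelStack:
    """Per-channel 3D intensity volumes, axis order (z, y, x)."""

    channels: tuple[np.ndarray, ...]
    voxel_xy: float = DEFAULT_PIXEL_SIZE
    z_step: float = DEFAULT_Z_STEP

    def __post_init__(self) -> None:
        chans = tuple(np.asarray(c, dtype=float) for c in self.channels)
        if not chans:
            raise ValueError("stack needs at least one channel")
        shape = chans[0].shape
        if any(c.shape != shape for c in chans):
            raise ValueError("channels must share a shape")
        if chans[0].ndim != 3 or min(shape) < 1:
            raise ValueError("channels must be non-empty 3D arrays")
        if self.voxel_xy <= 0 or self.z_step <= 0:
            raise ValueError("voxel dimensions must be positive")
        self.channels = chans

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels[0].shape

    def channel_sum(self) -> np.ndarray:
        return sum(self.channels[1:], start=self.channels[0].copy())

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Physical voxel spacing (z, y, x), µm."""
        return self.z_step, self.voxel_xy, self.voxel_xy


@dataclass
class GrowthParams:
    """Colony growth model: founder-cell sampling and size distribution."""

    median_diameter: float = DEFAULT_COLONY_MEDIAN_DIAMETER
    log_sigma: float = DEFAULT_COLONY_LOG_SIGMA
    density: float = DEFAULT_CELL_DENSITY
    #: if set, place exactly this many colonies per occupied droplet
    #: instead of sampling Poisson counts (used for exact-count tests).
    cells_per_droplet: Optional[int] = None

    def __post_init__(self) -> None:
        if self.median_diameter <= 0:
            raise ValueError("colony diameter distribution needs positive support")
        if self.log_sigma < 0:
            raise ValueError("log_sigma must be non-negative")


@dataclass
class NoiseParams:
    """Imaging model: background offset, linear gradient, additive noise."""

    background: float = 10.0
    gradient: float = 0.0          # intensity units per µm along x
    noise_scale: float = 2.0       # sd of additive Gaussian noise
    amplitude: float = 100.0       # peak intensity of one colony


@dataclass
class SyntheticScene:
    """A rendered scene plus everything needed to verify an analysis."""

    map: PrintingMap
    colonies: pd.DataFrame
    image: Micrograph
    stack: Optional[VoxelStack]
    rotation: float
    seed: int
    growth: GrowthParams = field(default_factory=GrowthParams)
    noise: NoiseParams = field(default_factory=NoiseParams)

    @property
    def n_colonies(self) -> int:
        return int((~self.colonies["is_debris"]).sum())

    def print_centre(self) -> tuple[float, float]:
        """Ground-truth centre of the print footprint on the canvas, µm."""
        m = CANVAS_MARGIN_DROPLETS * self.map.droplet_diameter
        w, h = self.map.extent
        return m + w / 2.0, m + h / 2.0


# ---------------------------------------------------------------------------
# Printing maps
# ---------------------------------------------------------------------------

def make_printing_map(
    n_x: int,
    n_y: int,
    pattern: str,
    *,
    mix_fraction: float = 0.5,
    strip_widths: Optional[Sequence[int]] = None,
    grid: Optional[np.ndarray] = None,
    droplet_diameter: float = DEFAULT_DROPLET_DIAMETER,
    pitch: Optional[float] = None,
) -> PrintingMap:
    """Build a printing map for a named two-genotype pattern.

    Patterns
    --------
    ``segregated-halves``
        The longer axis is split into two contiguous blocks, A then B,
        as equal as possible (fully segregated print, SI ~ 0.94).
    ``strips``
        Alternating A/B bands along the longer axis with the given
        ``strip_widths`` (droplet rows per band, cycled A,B,A,...).
        Intermediate-mixing layouts are approximate presets: the
        original band widths for SI = 0.67/0.80/0.88 are not published.
    ``checkerboard``
        A/B alternating per droplet.
    ``mixed``
        Every droplet is a MIXED 1:1 (or ``mix_fraction``) suspension
        of the two genotypes (well-mixed print, SI ~ 0.50).
    ``custom``
        Use ``grid`` verbatim.
    """
    if pitch is None:
        pitch = droplet_diameter
    shape = (n_y, n_x)
    if pattern == "segregated-halves":
        assignment = np.empty(shape, dtype=object)
        if n_y >= n_x:           # split along y (rows)
            half = n_y // 2
            assignment[:half, :] = "A"
            assignment[half:, :] = "B"
        else:
            half = n_x // 2
            assignment[:, :half] = "A"
            assignment[:, half:] = "B"
    elif pattern == "strips":
        if not strip_widths:
            raise ValueError("strips pattern requires strip_widths")
        assignment = np.empty(shape, dtype=object)
        axis_len = n_y if n_y >= n_x else n_x
        if sum(strip_widths) != axis_len:
            raise ValueError(
                f"strip widths {list(strip_widths)} must sum to the longer "
                f"axis length {axis_len}"
            )
        pos = 0
        for k, w in enumerate(strip_widths):
            lab = "A" if k % 2 == 0 else "B"
            if n_y >= n_x:
                assignment[pos:pos + w, :] = lab
            else:
                assignment[:, pos:pos + w] = lab
            pos += w
    elif pattern == "checkerboard":
        ii, jj = np.indices(shape)
        assignment = np.where((ii + jj) % 2 == 0, "A", "B").astype(object)
    elif pattern == "mixed":
        assignment = np.full(shape, "MIXED", dtype=object)
    elif pattern == "custom":
        if grid is None:
            raise ValueError("custom pattern requires a grid")
        assignment = np.asarray(grid, dtype=object)
        if assignment.shape != shape:
            raise ValueError(
                f"custom grid shape {assignment.shape} does not match "
                f"({n_y}, {n_x})"
            )
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return PrintingMap(
        n_x=n_x,
        n_y=n_y,
        assignment=assignment,
        droplet_diameter=droplet_diameter,
        pitch=pitch,
        mix_fraction=mix_fraction,
    )


# ---------------------------------------------------------------------------
# Reference rendering
# ---------------------------------------------------------------------------

def render_reference_image(
    pmap: PrintingMap,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    *,
    seed: int = 0,
):
    """Render the idealised reference mask of a printing map.

    Droplets become filled disks of ``droplet_diameter`` on the lattice;
    pixels inside an A (B) droplet are labelled A (B); pixels inside a
    MIXED droplet are labelled A with probability ``mix_fraction`` and B
    otherwise, independently per pixel (seeded); pixels outside every
    droplet carry no genotype.  Returns a
    :class:`printarray.segregation.GenotypeMask`.
    """
    from .segregation import GenotypeMask

    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if pixel_size > pmap.droplet_diameter:
        raise ValueError(
            "pixel_size exceeds the droplet diameter; droplets cannot be resolved"
        )
    width_um, height_um = pmap.extent
    nx = int(np.ceil(width_um / pixel_size))
    ny = int(np.ceil(height_um / pixel_size))
    labels = np.zeros((ny, nx), dtype=np.uint8)
    # pixel-centre coordinates, µm
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    X, Y = np.meshgrid(xs, ys)
    rng = np.random.default_rng(seed)
    r = pmap.droplet_diameter / 2.0
    centres = pmap.droplet_centres()
    flat = pmap.assignment.astype(str).ravel()
    for (cx, cy), lab in zip(centres, flat):
        if lab == "EMPTY":
            continue
        inside = (X - cx) ** 2 + (Y - cy) ** 2 <= r * r
        if lab == "A":
            labels[inside] = A
        elif lab == "B":
            labels[inside] = B
        else:  # MIXED
            n_in = int(inside.sum())
            draw = rng.random(n_in) < pmap.mix_fraction
            vals = np.where(draw, A, B).astype(np.uint8)
            labels[inside] = vals
    return GenotypeMask(labels=labels, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Cell seeding and colony growth
# ---------------------------------------------------------------------------

def droplet_volume_ml(diameter_um: float) -> float:
    """Volume of a spherical droplet in mL (1 mL = 1e12 µm³)."""
    r = diameter_um / 2.0
    return (4.0 / 3.0) * np.pi * r ** 3 / 1e12


def sample_initial_cells(
    pmap: PrintingMap,
    density: float = DEFAULT_CELL_DENSITY,
    seed: int = 0,
    *,
    cells_per_droplet: Optional[int] = None,
) -> pd.DataFrame:
    """Seed founder cells into every non-EMPTY droplet.

    Per droplet the cell count is Poisson with mean
    ``density × spherical droplet volume`` (~69.7 at 1e8 cells/mL in a
    110-µm droplet); positions are uniform over the droplet's circular
    footprint; genotypes follow the droplet's assignment, with MIXED
    droplets drawing each cell A with probability ``mix_fraction``.

    Returns a DataFrame with columns
    ``x_um, y_um, genotype, droplet_row, droplet_col``.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    rng = np.random.default_rng(seed)
    mean = density * droplet_volume_ml(pmap.droplet_diameter)
    r = pmap.droplet_diameter / 2.0
    centres = pmap.droplet_centres()
    flat = pmap.assignment.astype(str).ravel()
    rows = []
    for k, ((cx, cy), lab) in enumerate(zip(centres, flat)):
        if lab == "EMPTY":
            continue
        n = cells_per_droplet if cells_per_droplet is not None else rng.poisson(mean)
        if n == 0:
            continue
        # uniform in the disk footprint
        rad = r * np.sqrt(rng.random(n))
        ang = rng.uniform(0, 2 * np.pi, n)
        x = cx + rad * np.cos(ang)
        y = cy + rad * np.sin(ang)
        if lab == "MIXED":
            geno = np.where(rng.random(n) < pmap.mix_fraction, "A", "B")
        else:
            geno = np.full(n, lab)
        i, j = divmod(k, pmap.n_x)
        rows.append(pd.DataFrame({
            "x_um": x, "y_um": y, "genotype": geno,
            "droplet_row": i, "droplet_col": j,
        }))
    if not rows:
        return pd.DataFrame(
            columns=["x_um", "y_um", "genotype", "droplet_row", "droplet_col"]
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def _render_disks(shape, xs_px, ys_px, radii_px):
    """Sum of unit-amplitude filled disks on a float canvas (soft 1-px edge)."""
    img = np.zeros(shape, dtype=float)
    ny, nx = shape
    for x0, y0, rad in zip(xs_px, ys_px, radii_px):
        lo_r = max(int(np.floor(y0 - rad - 2)), 0)
        hi_r = min(int(np.ceil(y0 + rad + 2)) + 1, ny)
        lo_c = max(int(np.floor(x0 - rad - 2)), 0)
        hi_c = min(int(np.ceil(x0 + rad + 2)) + 1, nx)
        if lo_r >= hi_r or lo_c >= hi_c:
            continue
        yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        d = np.sqrt((xx - x0) ** 2 + (yy - y0) ** 2)
        img[lo_r:hi_r, lo_c:hi_c] += np.clip(rad - d + 0.5, 0.0, 1.0)
    return img


def _render_spheres(shape, xs_px, ys_px, zs_px, radii_xy_px, z_scale):
    """Sum of filled spheres in a (z, y, x) volume; z in slice units."""
    vol = np.zeros(shape, dtype=float)
    nz, ny, nx = shape
    for x0, y0, z0, rad in zip(xs_px, ys_px, zs_px, radii_xy_px):
        rad_z = rad / z_scale
        lo_z = max(int(np.floor(z0 - rad_z - 1)), 0)
        hi_z = min(int(np.ceil(z0 + rad_z + 1)) + 1, nz)
        lo_r = max(int(np.floor(y0 - rad - 1)), 0)
        hi_r = min(int(np.ceil(y0 + rad + 1)) + 1, ny)
        lo_c = max(int(np.floor(x0 - rad - 1)), 0)
        hi_c = min(int(np.ceil(x0 + rad + 1)) + 1, nx)
        if lo_z >= hi_z or lo_r >= hi_r or lo_c >= hi_c:
            continue
        zz, yy, xx = np.mgrid[lo_z:hi_z, lo_r:hi_r, lo_c:hi_c]
        d = np.sqrt(
            (xx - x0) ** 2 + (yy - y0) ** 2 + ((zz - z0) * z_scale) ** 2
        )
        vol[lo_z:hi_z, lo_r:hi_r, lo_c:hi_c] += np.clip(rad - d + 0.5, 0.0, 1.0)
    return vol


def render_scene(
    pmap: PrintingMap,
    growth: Optional[GrowthParams] = None,
    noise: Optional[NoiseParams] = None,
    rotation: float = 0.0,
    n_debris: int = 0,
    seed: int = 0,
    *,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    make_stack: bool = False,
    z_step: float = DEFAULT_Z_STEP,
) -> SyntheticScene:
    """Render a realistic micrograph (and optionally a stack) of a print.

    Founder cells from :func:`sample_initial_cells` become disk (2D) /
    sphere (3D) microcolonies whose diameters are log-normal with the
    requested population median; each colony emits intensity only in its
    genotype's channel; the whole print is rotated by ``rotation``
    degrees about its centroid; ``n_debris`` extra colonies land outside
    the print footprint.  The full ground truth is retained on the
    returned scene.
    """
    growth = growth or GrowthParams()
    noise = noise or NoiseParams()
    root = np.random.SeedSequence(seed)
    seed_cells, seed_sizes, seed_debris, seed_noise = root.spawn(4)

    cells = sample_initial_cells(
        pmap, growth.density,
        seed=seed_cells,
        cells_per_droplet=growth.cells_per_droplet,
    )
    margin = CANVAS_MARGIN_DROPLETS * pmap.droplet_diameter
    width_um, height_um = pmap.extent
    canvas_w = width_um + 2 * margin
    canvas_h = height_um + 2 * margin
    cx0, cy0 = margin + width_um / 2.0, margin + height_um / 2.0

    x = cells["x_um"].to_numpy() + margin
    y = cells["y_um"].to_numpy() + margin
    if rotation:
        th = np.deg2rad(rotation)
        dx, dy = x - cx0, y - cy0
        x = cx0 + dx * np.cos(th) - dy * np.sin(th)
        y = cy0 + dx * np.sin(th) + dy * np.cos(th)

    rng_sizes = np.random.default_rng(seed_sizes)
    n = len(cells)
    diam = np.exp(
        np.log(growth.median_diameter)
        + growth.log_sigma * rng_sizes.standard_normal(n)
    )

    colonies = pd.DataFrame({
        "x_um": x,
        "y_um": y,
        "genotype": cells["genotype"].to_numpy() if n else np.array([], dtype=object),
        "diameter_um": diam,
        "droplet_row": cells["droplet_row"].to_numpy() if n else np.array([], int),
        "droplet_col": cells["droplet_col"].to_numpy() if n else np.array([], int),
        "is_debris": np.zeros(n, dtype=bool),
    })

    if n_debris:
        rng_debris = np.random.default_rng(seed_debris)
        # debris sits towards the canvas corners, clearly beyond the
        # print's radial footprint so isolation can separate it
        half_diag = np.hypot(width_um, height_um) / 2.0
        corner_r = np.hypot(canvas_w, canvas_h) / 2.0
        rad = rng_debris.uniform(0.5 * (half_diag + corner_r),
                                 0.95 * corner_r, n_debris)
        corner = rng_debris.integers(0, 4, n_debris)
        base = np.arctan2(canvas_h, canvas_w)
        ang = (np.array([base, np.pi - base, np.pi + base, -base])[corner]
               + rng_debris.uniform(-0.05, 0.05, n_debris))
        dx = np.clip(cx0 + rad * np.cos(ang), 2.0, canvas_w - 2.0)
        dy = np.clip(cy0 + rad * np.sin(ang), 2.0, canvas_h - 2.0)
        dd = np.exp(
            np.log(growth.median_diameter)
            + growth.log_sigma * rng_debris.standard_normal(n_debris)
        )
        dg = np.where(rng_debris.random(n_debris) < 0.5, "A", "B")
        colonies = pd.concat([colonies, pd.DataFrame({
            "x_um": dx, "y_um": dy, "genotype": dg, "diameter_um": dd,
            "droplet_row": -1, "droplet_col": -1,
            "is_debris": np.ones(n_debris, dtype=bool),
        })], ignore_index=True)

    nx = int(np.ceil(canvas_w / pixel_size))
    ny = int(np.ceil(canvas_h / pixel_size))
    xs_px = colonies["x_um"].to_numpy() / pixel_size - 0.5
    ys_px = colonies["y_um"].to_numpy() / pixel_size - 0.5
    radii_px = colonies["diameter_um"].to_numpy() / 2.0 / pixel_size

    rng_noise = np.random.default_rng(seed_noise)
    chans = []
    for geno in ("A", "B"):
        sel = (colonies["genotype"] == geno).to_numpy()
        img = noise.amplitude * _render_disks(
            (ny, nx), xs_px[sel], ys_px[sel], radii_px[sel]
        )
        img += noise.background
        if noise.gradient:
            img += noise.gradient * (np.arange(nx) * pixel_size)[None, :]
        if noise.noise_scale:
            img += noise.noise_scale * rng_noise.standard_normal((ny, nx))
        chans.append(np.clip(img, 0.0, None))
    image = Micrograph(channels=(chans[0], chans[1]), pixel_size=pixel_size)

    stack = None
    if make_stack:
        nz = max(int(np.ceil(pmap.droplet_diameter / z_step)), 1)
        z_mid = (nz - 1) / 2.0
        z_scale = z_step / pixel_size
        vols = []
        for geno in ("A", "B"):
            sel = (colonies["genotype"] == geno).to_numpy()
            vol = noise.amplitude * _render_spheres(
                (nz, ny, nx), xs_px[sel], ys_px[sel],
                np.full(int(sel.sum()), z_mid), radii_px[sel], z_scale,
            )
            vol += noise.background
            if noise.noise_scale:
                vol += noise.noise_scale * rng_noise.standard_normal((nz, ny, nx))
            vols.append(np.clip(vol, 0.0, None))
        stack = VoxelStack(channels=tuple(vols), voxel_xy=pixel_size, z_step=z_step)

    return SyntheticScene(
        map=pmap, colonies=colonies, image=image, stack=stack,
        rotation=rotation, seed=seed, growth=growth, noise=noise,
    )


# ---------------------------------------------------------------------------
# Small presets used by the segmentation tests
# ---------------------------------------------------------------------------

def one_colony_per_droplet_scene(
    pmap: PrintingMap,
    *,
    diameter_um: float = 15.0,
    noise: Optional[NoiseParams] = None,
    seed: int = 0,
) -> SyntheticScene:
    """One fixed-size colony at each droplet centre (non-touching preset)."""
    growth = GrowthParams(
        median_diameter=diameter_um, log_sigma=0.0, cells_per_droplet=1
    )
    scene = render_scene(pmap, growth, noise or NoiseParams(noise_scale=0.0),
                         seed=seed)
    # snap each colony to its droplet centre for exact geometry
    margin = CANVAS_MARGIN_DROPLETS * pmap.droplet_diameter
    centres = pmap.droplet_centres()
    flat = pmap.assignment.astype(str).ravel()
    keep = flat != "EMPTY"
    n = int(keep.sum())
    genos = np.where(
        flat[keep] == "MIXED",
        np.where(np.random.default_rng(seed).random(n) < pmap.mix_fraction,
                 "A", "B"),
        flat[keep],
    )
    colonies = pd.DataFrame({
        "x_um": centres[keep, 0] + margin,
        "y_um": centres[keep, 1] + margin,
        "genotype": genos,
        "diameter_um": np.full(n, float(diameter_um)),
        "droplet_row": np.arange(len(flat))[keep] // pmap.n_x,
        "droplet_col": np.arange(len(flat))[keep] % pmap.n_x,
        "is_debris": np.zeros(n, dtype=bool),
    })
    scene = replace(scene, colonies=colonies)
    return _rerender(scene)


def _rerender(scene: SyntheticScene) -> SyntheticScene:
    """Re-draw the image channels from the scene's colony table."""
    px = scene.image.pixel_size
    ny, nx = scene.image.shape
    xs = scene.colonies["x_um"].to_numpy() / px - 0.5
    ys = scene.colonies["y_um"].to_numpy() / px - 0.5
    rr = scene.colonies["diameter_um"].to_numpy() / 2.0 / px
    rng = np.random.default_rng(np.random.SeedSequence(scene.seed).spawn(4)[3])
    chans = []
    for geno in ("A", "B"):
        sel = (scene.colonies["genotype"] == geno).to_numpy()
        img = scene.noise.amplitude * _render_disks((ny, nx), xs[sel], ys[sel], rr[sel])
        img += scene.noise.background
        if scene.noise.noise_scale:
            img += scene.noise.noise_scale * rng.standard_normal((ny, nx))
        chans.append(np.clip(img, 0.0, None))
    return replace(scene, image=Micrograph(channels=(chans[0], chans[1]),
                                           pixel_size=px))


def touching_pair_image(
    *,
    gap_px: float = 3.0,
    radius_px: float = 8.0,
    amplitude: float = 100.0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> Micrograph:
    """Two bright disks separated by a dark gap of about one colony scale."""
    size = int(6 * radius_px + gap_px + 10)
    cy = size / 2.0
    cx1 = size / 2.0 - radius_px - gap_px / 2.0
    cx2 = size / 2.0 + radius_px + gap_px / 2.0
    img = amplitude * _render_disks((size, size), [cx1, cx2], [cy, cy],
                                    [radius_px, radius_px])
    zero = np.zeros_like(img)
    return Micrograph(channels=(img, zero), pixel_size=pixel_size)


def sphere_stack(
    centres: Sequence[tuple[float, float, float]],
    radii_um: Sequence[float],
    *,
    shape: tuple[int, int, int],
    voxel_xy: float = DEFAULT_PIXEL_SIZE,
    z_step: float = DEFAULT_Z_STEP,
    amplitude: float = 100.0,
    background: float = 0.0,
) -> VoxelStack:
    """Bright spheres at physical centres (x, y, z µm) in a dark volume."""
    xs = [c[0] / voxel_xy - 0.5 for c in centres]
    ys = [c[1] / voxel_xy - 0.5 for c in centres]
    zs = [c[2] / z_step - 0.5 for c in centres]
    rr = [r / voxel_xy for r in radii_um]
    vol = amplitude * _render_spheres(shape, xs, ys, zs, rr, z_step / voxel_xy)
    vol += background
    return VoxelStack(channels=(vol,), voxel_xy=voxel_xy, z_step=z_step)


def touching_sphere_stack(
    *,
    radius_um: float = 12.0,
    overlap: float = 0.9,
    dim_factor: float = 0.6,
    voxel_xy: float = 2.0,
    z_step: float = 2.73,
    amplitude: float = 100.0,
) -> tuple[VoxelStack, int]:
    """Two closely packed bright spheres joined across a dim interface.

    The sphere centres sit ``2 * overlap * radius`` apart so the pair
    forms one bright body, and the contact plane is dimmed to
    ``dim_factor`` of the amplitude - dark relative to the colony
    interiors but still above a plain intensity threshold, so a rough
    segmentation merges the pair while the interface's positive
    principal curvature remains detectable.  Returns the stack and the
    ground-truth sphere count (2).
    """
    sep = 2.0 * overlap * radius_um
    nx = int(np.ceil((sep + 6 * radius_um) / voxel_xy))
    ny = int(np.ceil(6 * radius_um / voxel_xy))
    nz = max(int(np.ceil(4 * radius_um / z_step)), 5)
    cy = ny * voxel_xy / 2.0
    cz = nz * z_step / 2.0
    mid = nx * voxel_xy / 2.0
    cx1, cx2 = mid - sep / 2.0, mid + sep / 2.0
    stack = sphere_stack(
        [(cx1, cy, cz), (cx2, cy, cz)], [radius_um, radius_um],
        shape=(nz, ny, nx), voxel_xy=voxel_xy, z_step=z_step,
        amplitude=amplitude,
    )
    vol = np.minimum(stack.channels[0], amplitude)  # union, not sum
    xs = (np.arange(nx) + 0.5) * voxel_xy
    in_plane = np.abs(xs - mid) <= voxel_xy
    vol[:, :, in_plane] *= dim_factor
    return VoxelStack(channels=(vol,), voxel_xy=voxel_xy, z_step=z_step), 2


# ---------------------------------------------------------------------------
# Tabular simulators for the outcome metrics
# ---------------------------------------------------------------------------

def simulate_flow_events(
    n_events: int,
    freq_a: float,
    seed: int = 0,
    *,
    fluor_bright: float = 2 ** 12.0,
    fluor_dim: float = 2 ** 7.0,
    fluor_cv: float = 0.25,
) -> pd.DataFrame:
    """Flow-cytometry event list with two well-separated fluorescence modes.

    Genotype-1 events (fraction ``freq_a``) are log-normally bright,
    genotype-2 events dim; forward/side scatter form a single core
    population with a 5% tail of outliers.
    """
    rng = np.random.default_rng(seed)
    is_a = rng.random(n_events) < freq_a
    mode = np.where(is_a, fluor_bright, fluor_dim)
    fluor = mode * np.exp(fluor_cv * rng.standard_normal(n_events))
    fsc = 5e4 * np.exp(0.15 * rng.standard_normal(n_events))
    ssc = 2e4 * np.exp(0.15 * rng.standard_normal(n_events))
    out = rng.random(n_events) < 0.05
    fsc[out] *= rng.uniform(3, 10, int(out.sum()))
    ssc[out] *= rng.uniform(3, 10, int(out.sum()))
    return pd.DataFrame({"fsc": fsc, "ssc": ssc, "fluor": fluor})


def simulate_growth_curve(
    doubling_min: float = 30.0,
    *,
    od0: float = 0.01,
    od_max: float = 1.2,
    t_max_min: float = 1440.0,
    dt_min: float = 5.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """OD trace sampled every ``dt_min`` minutes.

    Exponential at rate ln2/doubling_min up to the carrying capacity
    ``od_max`` (where growth stops), so the 0.2-0.7 window used for
    doubling-time fits is genuinely exponential; optional multiplicative
    noise.
    """
    t = np.arange(0.0, t_max_min + dt_min, dt_min)
    r = np.log(2.0) / doubling_min
    od = np.minimum(od_max, od0 * np.exp(r * t))
    if noise_cv:
        rng = np.random.default_rng(seed)
        od = od * np.exp(noise_cv * rng.standard_normal(len(t)))
    return pd.DataFrame({"time_min": t, "od": od})
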