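"""Per-pixel genotype assignment and the segregation index SI(h).

The segregation index measures genetic mixing in a two-genotype
community image on a chosen spatial scale.  Each genotype-bearing pixel
``i`` gets a local index ``s_i(h)``: the fraction of genotype-bearing
pixels within ``h`` rows or columns of ``i`` (a square neighbourhood of
half-width ``h``, the focal pixel included) that share ``i``'s genotype.
The global index ``SI(h)`` is the arithmetic mean of ``s_i(h)`` over all
``M`` focal pixels.  SI runs from ~0.5 (the two genotypes fully mixed on
scale ``h``) to 1.0 (no mixing).

Neighbourhoods are square, clipped at image borders; pixels carrying no
genotype are never counted.  The implementation uses summed-area tables
and is checked against a direct per-pixel double loop in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .synthgen import NONE, A, B, Micrograph, PrintingMap

__all__ = [
    "GenotypeMask", "SIProfile", "assign_pixel_genotypes",
    "local_si", "global_si", "si_profile", "compare_to_reference",
    "PAPER_SPANS_PX",
]

#: neighbourhood half-widths used for printing-fidelity profiles, px
#: (7.6, 15.2, 30.3, 75.8, 151.5 µm at 1.515 µm/px).
PAPER_SPANS_PX = (5, 10, 20, 50, 100)


@dataclass
class GenotypeMask:
    """Per-pixel genotype labels: 0 = none, 1 = A, 2 = B."""

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.labels.max(initial=0) > B:
            raise ValueError("labels must come from {0, 1, 2}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def genotype_areas(self) -> dict[str, float]:
        """Total cross-sectional area per genotype, µm²."""
        px2 = self.pixel_size ** 2
        return {
            "A": float((self.labels == A).sum()) * px2,
            "B": float((self.labels == B).sum()) * px2,
        }


@dataclass
class SIProfile:
    """SI(h) evaluated at a series of neighbourhood spans."""

    spans_px: np.ndarray
    spans_um: np.ndarray
    si: np.ndarray
    m: np.ndarray           # focal-pixel count per span

    def __post_init__(self) -> None:
        self.spans_px = np.asarray(self.spans_px, dtype=int)
        self.spans_um = np.asarray(self.spans_um, dtype=float)
        self.si = np.asarray(self.si, dtype=float)
        self.m = np.asarray(self.m, dtype=int)
        if not np.all(np.diff(self.spans_px) > 0):
            raise ValueError("spans must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "span_px": self.spans_px,
            "span_um": self.spans_um,
            "si": self.si,
            "m": self.m,
        })


# ---------------------------------------------------------------------------
# Genotype assignment
# ---------------------------------------------------------------------------

def assign_pixel_genotypes(
    img: Micrograph,
    *,
    thresholds: Optional[tuple[float, float]] = None,
    log_transform: bool = True,
) -> GenotypeMask:
    """Classify every pixel as genotype A, B or neither.

    Each fluorescence channel is thresholded separately with Otsu's
    method (or the explicit ``thresholds`` override).  A pixel is A if
    only channel 1 exceeds its threshold, B if only channel 2 does, and
    carries no genotype when both or neither channel exceeds it.

    By default Otsu runs on log(1 + I): fluorescence intensities are
    heavy-tailed where microcolonies overlap in projection, and the log
    transform keeps the background/signal split stable against that
    tail.  Set ``log_transform=False`` for plain linear-scale Otsu.
    Explicit ``thresholds`` are always on the raw intensity scale.
    """
    from skimage.filters import threshold_otsu

    c1, c2 = img.channels
    if thresholds is None:
        ts = []
        for k, c in enumerate((c1, c2)):
            if np.ptp(c) == 0:
                raise ValueError(
                    f"channel {k + 1} is constant; Otsu threshold is undefined "
                    "(pass explicit thresholds)"
                )
            if log_transform:
                ts.append(float(np.expm1(threshold_otsu(np.log1p(c)))))
            else:
                ts.append(float(threshold_otsu(c)))
        t1, t2 = ts
    else:
        t1, t2 = thresholds
    above1 = c1 > t1
    above2 = c2 > t2
    labels = np.zeros(c1.shape, dtype=np.uint8)
    labels[above1 & ~above2] = A
    labels[above2 & ~above1] = B
    return GenotypeMask(labels=labels, pixel_size=img.pixel_size)


# ---------------------------------------------------------------------------
# SI computation
# ---------------------------------------------------------------------------

def _box_counts(binary: np.ndarray, h: int) -> np.ndarray:
    """Per-pixel count of true cells in the (2h+1)² window, border-clipped."""
    ny, nx = binary.shape
    c = np.zeros((ny + 1, nx + 1), dtype=np.int64)
    np.cumsum(np.cumsum(binary, axis=0), axis=1, out=c[1:, 1:])
    r = np.arange(ny)
    col = np.arange(nx)
    r0 = np.clip(r - h, 0, ny)
    r1 = np.clip(r + h + 1, 0, ny)
    c0 = np.clip(col - h, 0, nx)
    c1 = np.clip(col + h + 1, 0, nx)
    return (
        c[np.ix_(r1, c1)] - c[np.ix_(r0, c1)]
        - c[np.ix_(r1, c0)] + c[np.ix_(r0, c0)]
    )


def local_si(
    mask: GenotypeMask, h: int, *, include_self: bool = True
) -> np.ndarray:
    """Local segregation index s_i(h) for every genotype-bearing pixel.

    Returns a float array of the mask's shape with NaN at pixels that
    carry no genotype.  ``include_self`` controls whether the focal
    pixel counts among its own neighbours (default: yes, which keeps
    ``s_i`` defined for isolated pixels).
    """
    if h < 1:
        raise ValueError("h must be >= 1")
    is_a = mask.labels == A
    is_b = mask.labels == B
    if not (is_a.any() or is_b.any()):
        raise ValueError("mask contains no genotype-bearing pixels")
    n_a = _box_counts(is_a, h)
    n_b = _box_counts(is_b, h)
    kin = np.where(is_a, n_a, n_b).astype(float)
    total = (n_a + n_b).astype(float)
    if not include_self:
        kin -= 1.0
        total -= 1.0
    out = np.full(mask.shape, np.nan)
    focal = is_a | is_b
    with np.errstate(invalid="ignore", divide="ignore"):
        out[focal] = kin[focal] / total[focal]
    return out


def global_si(
    mask: GenotypeMask, h: int, *, include_self: bool = True
) -> tuple[float, int]:
    """Global SI(h): mean local index over the M focal pixels.

    Returns ``(SI, M)``.
    """
    s = local_si(mask, h, include_self=include_self)
    vals = s[~np.isnan(s)]
    m = int(vals.size)
    if m == 0:
        raise ValueError("no focal pixels with a defined local index")
    return float(vals.mean()), m


def si_profile(
    mask: GenotypeMask,
    spans_px: Optional[Sequence[int]] = None,
    *,
    spans_um: Optional[Sequence[float]] = None,
    include_self: bool = True,
) -> SIProfile:
    """Evaluate SI over a series of neighbourhood spans.

    Spans may be given in pixels or µm; a span of S µm means
    ``h = round(S / pixel_size)`` px.
    """
    if (spans_px is None) == (spans_um is None):
        raise ValueError("give exactly one of spans_px or spans_um")
    if spans_px is None:
        hs = [int(round(s / mask.pixel_size)) for s in spans_um]
    else:
        hs = [int(s) for s in spans_px]
    if not hs:
        raise ValueError("span list is empty")
    si = []
    m = []
    for h in hs:
        v, cnt = global_si(mask, h, include_self=include_self)
        si.append(v)
        m.append(cnt)
    return SIProfile(
        spans_px=np.array(hs),
        spans_um=np.array(hs, dtype=float) * mask.pixel_size,
        si=np.array(si),
        m=np.array(m),
    )


def compare_to_reference(
    measured: SIProfile,
    pmap: PrintingMap,
    *,
    pixel_size: Optional[float] = None,
    seed: int = 0,
) -> tuple["object", float]:
    """Compare a measured SI profile against the printing map's ideal.

    Renders the idealised reference mask for ``pmap``, computes its SI
    profile on the same spans, and returns a paired DataFrame
    (span, measured, reference, delta) plus the maximum |ΔSI|.
    """
    from .synthgen import render_reference_image

    px = pixel_size if pixel_size is not None else float(
        measured.spans_um[0] / measured.spans_px[0]
    )
    ref_mask = render_reference_image(pmap, px, seed=seed)
    ref = si_profile(ref_mask, spans_px=list(measured.spans_px))
    if not np.array_equal(ref.spans_px, measured.spans_px):
        raise ValueError("span lists do not match")
    import pandas as pd

    paired = pd.DataFrame({
        "span_px": measured.spans_px,
        "span_um": measured.spans_um,
        "si_measured": measured.si,
        "si_reference": ref.si,
        "delta": measured.si - ref.si,
    })
    return paired, float(np.abs(paired["delta"]).max())
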