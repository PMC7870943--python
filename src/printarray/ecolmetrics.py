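"""Ecological outcome metrics for printed-community competitions.

Two headline metrics summarise an 18-h competition between genotypes a
and b:

* frequency  f = A_a / (A_a + A_b)
* productivity  p = A_a / A_S

where A is a genotype's total abundance on any consistent basis
(2D cross-sectional area, 3D volume, cell counts or CFU) and A_S is the
abundance reached by a matched susceptible genotype growing in the same
pattern but without interference competition.  The module also covers
the two tabular calculations used alongside imaging: flow-cytometry
event gating (core scatter gate, fluorescence split, first-N counting)
and doubling time from the exponential window of an OD growth curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceRecord", "CompetitionResult", "frequency", "productivity",
    "gate_flow_events", "doubling_time",
    "DEFAULT_FLUOR_THRESHOLD", "DEFAULT_N_KEEP",
]

#: fluorescence split between the bright and dim genotype (2^9.5).
DEFAULT_FLUOR_THRESHOLD = 2.0 ** 9.5
#: number of gated events used for frequency estimation.
DEFAULT_N_KEEP = 3000

VALID_BASES = {"area_um2", "volume_um3", "cells", "cfu"}


@dataclass
class AbundanceRecord:
    """A genotype's total abundance on a stated basis."""

    genotype: str
    abundance: float
    basis: str

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")
        if self.basis not in VALID_BASES:
            raise ValueError(
                f"unknown basis {self.basis!r}; expected one of {sorted(VALID_BASES)}"
            )


@dataclass
class CompetitionResult:
    """Per-genotype frequencies (and optional productivities)."""

    frequencies: dict[str, float]
    productivities: dict[str, float] | None = None
    reference_abundance: float | None = None
    counts: dict[str, int] | None = None

    def to_dict(self) -> dict:
        out: dict = {"frequencies": self.frequencies}
        if self.productivities is not None:
            out["productivities"] = self.productivities
            out["reference_abundance"] = self.reference_abundance
        if self.counts is not None:
            out["counts"] = self.counts
        return out


def _check_same_basis(a: AbundanceRecord, b: AbundanceRecord) -> None:
    if a.basis != b.basis:
        raise ValueError(
            f"abundance bases differ ({a.basis!r} vs {b.basis!r}); "
            "frequencies must compare like with like"
        )


def frequency(a: AbundanceRecord, b: AbundanceRecord) -> CompetitionResult:
    """Frequency of each genotype: f_a = A_a / (A_a + A_b)."""
    _check_same_basis(a, b)
    total = a.abundance + b.abundance
    if total <= 0:
        raise ValueError("total abundance is zero; frequency is undefined")
    f_a = a.abundance / total
    return CompetitionResult(frequencies={a.genotype: f_a, b.genotype: 1.0 - f_a})


def productivity(a: AbundanceRecord, reference: AbundanceRecord) -> float:
    """Productivity p = A_a / A_S against a no-interference control.

    The reference abundance must come from a matched experiment (same
    starting density and spatial pattern, no interference competition);
    it is always supplied explicitly, never inferred.
    """
    _check_same_basis(a, reference)
    if reference.abundance <= 0:
        raise ValueError("reference abundance A_S must be positive")
    return a.abundance / reference.abundance


# ---------------------------------------------------------------------------
# Flow cytometry
# ---------------------------------------------------------------------------

def gate_flow_events(
    events: pd.DataFrame,
    core_quantile: float = 0.9,
    fluor_threshold: float = DEFAULT_FLUOR_THRESHOLD,
    n_keep: int = DEFAULT_N_KEEP,
) -> CompetitionResult:
    """Count genotypes among gated flow events and compute frequency.

    The core gate is an axis-aligned box containing the central
    ``core_quantile`` of events in each of forward and side scatter
    (outlier trimming to minimise count biases).  Within the gate,
    events with fluorescence above ``fluor_threshold`` are genotype-1
    and the rest genotype-2.  Only the first ``n_keep`` gated events, in
    input (acquisition) order, are counted; if fewer pass the gate, all
    are used and a warning is recorded.

    ``events`` needs columns ``fsc``, ``ssc``, ``fluor``.  The returned
    result carries counts in ``productivities``-free form: frequencies
    keyed ``genotype_1`` / ``genotype_2``.
    """
    if fluor_threshold <= 0:
        raise ValueError("fluor_threshold must be positive")
    if n_keep < 1:
        raise ValueError("n_keep must be at least 1")
    if not 0 < core_quantile <= 1:
        raise ValueError("core_quantile must lie in (0, 1]")
    fsc = events["fsc"].to_numpy(dtype=float)
    ssc = events["ssc"].to_numpy(dtype=float)
    fluor = events["fluor"].to_numpy(dtype=float)
    lo_q, hi_q = (1 - core_quantile) / 2, 1 - (1 - core_quantile) / 2
    in_gate = np.ones(len(events), dtype=bool)
    for axis in (fsc, ssc):
        lo, hi = np.quantile(axis, [lo_q, hi_q])
        in_gate &= (axis >= lo) & (axis <= hi)
    gated = np.flatnonzero(in_gate)
    if gated.size == 0:
        raise ValueError("no events pass the core gate")
    if gated.size < n_keep:
        warnings.warn(
            f"only {gated.size} gated events available (< n_keep={n_keep}); "
            "using all of them",
            stacklevel=2,
        )
    kept = gated[:n_keep]
    n1 = int((fluor[kept] > fluor_threshold).sum())
    n2 = int(kept.size - n1)
    res = frequency(
        AbundanceRecord("genotype_1", float(n1), "cells"),
        AbundanceRecord("genotype_2", float(n2), "cells"),
    )
    return CompetitionResult(
        frequencies=res.frequencies,
        counts={"genotype_1": n1, "genotype_2": n2},
    )


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

def doubling_time(
    curve: pd.DataFrame,
    od_low: float = 0.2,
    od_high: float = 0.7,
) -> float:
    """Doubling time (min) from the exponential window of a growth curve.

    Fits ln(OD) against time by least squares over the points with
    ``od_low <= OD <= od_high`` (exponential phase) and returns
    ln(2)/slope.  ``curve`` needs columns ``time_min`` and ``od``
    (background-subtracted), with strictly increasing times.
    """
    t = curve["time_min"].to_numpy(dtype=float)
    od = curve["od"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    window = (od >= od_low) & (od <= od_high)
    if window.sum() < 3:
        raise ValueError(
            f"fewer than 3 points with OD in [{od_low}, {od_high}]"
        )
    slope = np.polyfit(t[window], np.log(od[window]), 1)[0]
    if slope <= 1e-12:  # flat or declining, up to fit round-off
        raise ValueError("non-positive growth rate inside the fit window")
    return float(np.log(2.0) / slope)
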