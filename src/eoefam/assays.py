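"""Bench-assay quantification formulas.

Pure functions reproducing the readout arithmetic of three in-vitro assays on
pre-measured quantities: scratch-wound closure (areas from image analysis),
calpain-14-mediated protein degradation (western-blot band intensities) and
immunofluorescence (ImageJ-style corrected total fluorescence).  All are
dimensionless percentages or intensity differences; no image processing
happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "wound_closure_pct",
    "protein_remaining_pct",
    "total_protein_pct",
    "CorrectedFluorescence",
    "corrected_total_fluorescence",
]


def wound_closure_pct(w0: float, wt: float) -> float:
    """Percent change in wound area: 100 x (W0 - Wt) / W0.

    ``w0`` is the wound width/area at time zero, ``wt`` at the endpoint (8 or
    12 h).  Negative values mean the gap widened.  Scale-invariant: measuring
    both widths in different units leaves the result unchanged.
    """
    if w0 <= 0:
        raise ValueError("w0 must be > 0")
    if wt < 0:
        raise ValueError("wt must be >= 0")
    return 100.0 * (w0 - wt) / w0


def protein_remaining_pct(before: float, after: float) -> float:
    """Protein remaining after calpain activation: 100 x after / before,
    from band intensities before/after adding calcium."""
    if before <= 0:
        raise ValueError("band intensity before activation must be > 0")
    if after < 0:
        raise ValueError("band intensity after activation must be >= 0")
    return 100.0 * after / before


def total_protein_pct(
    sample_remaining: float, nonvariant_remaining_values: Sequence[float]
) -> float:
    """Total protein as a percentage of the non-variant reference:
    100 x sample / mean(non-variant remaining values)."""
    if not nonvariant_remaining_values:
        raise ValueError("reference set is empty")
    ref = sum(nonvariant_remaining_values) / len(nonvariant_remaining_values)
    if ref <= 0:
        raise ValueError("reference mean must be > 0")
    return 100.0 * sample_remaining / ref


@dataclass(frozen=True)
class CorrectedFluorescence:
    value: float
    low_signal: bool  # True when the background subtraction went negative


def corrected_total_fluorescence(
    integrated_density: float, area: float, mean_background: float
) -> CorrectedFluorescence:
    """ImageJ-style corrected total fluorescence:
    integrated density − (selected area x mean background fluorescence).

    A negative result (signal below background) is retained but flagged
    ``low_signal`` rather than clipped.
    """
    if area < 0:
        raise ValueError("area must be >= 0")
    value = integrated_density - area * mean_background
    return CorrectedFluorescence(value=value, low_signal=value < 0)
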