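"""Standard-curve qPCR quantification of minigene copy numbers.

A dilution series of known template copies gives a straight line of Ct on
log10(copies); amplification efficiency derives from the slope as
``10^(-1/slope) - 1`` (a perfect doubling per cycle gives slope -1/log10(2)
= -3.3219 and efficiency 1).  Sample copies invert the line, and cell-ratio
estimates between two minigene-bearing populations are corrected for each
line's average integrations per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["StandardCurve", "CopyEstimate", "fit_standard_curve",
           "quantify_copies", "corrected_cell_ratio", "one_tailed_ttest"]


@dataclass(frozen=True)
class StandardCurve:
    slope: float          # Ct per log10(copies); negative for valid curves
    intercept: float      # Ct at 1 copy
    r2: float
    efficiency: float     # 10^(-1/slope) - 1

    def ct_to_copies(self, ct: float) -> float:
        return float(10.0 ** ((ct - self.intercept) / self.slope))


@dataclass(frozen=True)
class CopyEstimate:
    copies: float
    replicate_cv: Optional[float] = None

    def __post_init__(self) -> None:
        if self.copies <= 0:
            raise ValueError("copies must be positive")


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Ct on log10(copies) over a dilution series.

    ``points`` are (copies, Ct) pairs; at least 3 distinct copy levels are
    required (the assay uses a 5-point series from 1e5 down to 1e2 copies).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 standard points")
    copies = np.array([c for c, _ in points], dtype=float)
    cts = np.array([ct for _, ct in points], dtype=float)
    if (copies <= 0).any():
        raise ValueError("copy numbers must be positive")
    if len(np.unique(copies)) < 3:
        raise ValueError("need at least 3 distinct copy levels")
    fit = stats.linregress(np.log10(copies), cts)
    slope = float(fit.slope)
    if slope == 0:
        raise ValueError("degenerate standard curve (zero slope)")
    return StandardCurve(slope=slope, intercept=float(fit.intercept),
                         r2=float(fit.rvalue ** 2),
                         efficiency=float(10.0 ** (-1.0 / slope) - 1.0))


def quantify_copies(ct: Optional[float], curve: StandardCurve,
                    replicates: Sequence[float] = ()) -> CopyEstimate:
    """Invert the standard curve: copies = 10^((ct - intercept)/slope).

    With technical ``replicates`` (a list of Ct values), the estimate is the
    mean of per-replicate copies and the CV (sd/mean, ddof=1) is reported;
    ``ct`` may then be omitted.
    """
    if replicates is not None and len(replicates) > 0:
        per_rep = np.array([curve.ct_to_copies(c) for c in replicates])
        mean = float(per_rep.mean())
        cv = float(per_rep.std(ddof=1) / mean) if len(per_rep) > 1 else None
        return CopyEstimate(copies=mean, replicate_cv=cv)
    if ct is None:
        raise ValueError("either ct or replicates must be given")
    return CopyEstimate(copies=curve.ct_to_copies(ct))


def corrected_cell_ratio(copies_a: float, copies_b: float,
                         integrations_per_cell_a: float,
                         integrations_per_cell_b: float) -> float:
    """Fraction of cells belonging to population A, given measured minigene
    copies and each transduced line's average integrations per cell.

    cells_x = copies_x / integrations_x; returns cells_a/(cells_a + cells_b).
    """
    if copies_a <= 0 or copies_b <= 0:
        raise ValueError("copy numbers must be positive")
    if integrations_per_cell_a <= 0 or integrations_per_cell_b <= 0:
        raise ValueError("integrations per cell must be positive")
    cells_a = copies_a / integrations_per_cell_a
    cells_b = copies_b / integrations_per_cell_b
    return cells_a / (cells_a + cells_b)


def one_tailed_ttest(x: Sequence[float], y: Sequence[float]):
    """Unpaired one-tailed Student's t test (H1: mean(x) > mean(y)) plus
    Cohen's d; the standard formulas, provided as a convenience for replicate
    ratio vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, p = stats.ttest_ind(x, y, equal_var=True, alternative="greater")
    nx, ny = len(x), len(y)
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    d = (x.mean() - y.mean()) / pooled if pooled > 0 else np.inf
    return float(t), float(p), float(d)
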