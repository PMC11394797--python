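"""Partition-coefficient estimation from dilution series.

In a dilution-series partitioning experiment, increasing amounts of protein
are loaded into replicate two-phase systems and the protein concentration
(here a fluorescence signal proportional to it) is measured in both phases.
Because K = [top]/[bottom] is independent of load, the top-phase signal is
linear in the bottom-phase signal and K is the slope of that line.  The
default fit includes an intercept, which absorbs background signal; a
through-origin fit is available.  Replicate K values are averaged and their
spread checked against the 3% reproducibility bound typical of the assay.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "DilutionSeries",
    "KEstimate",
    "KAverage",
    "DegenerateDesignError",
    "NonPhysicalKError",
    "ReproducibilityWarning",
    "estimate_k",
    "average_k",
    "REPRODUCIBILITY_TOLERANCE",
]

#: Replicate K values deviating from their mean by more than this fraction
#: are flagged; partitioning assays of this type reproduce to within 3%.
REPRODUCIBILITY_TOLERANCE = 0.03


class DegenerateDesignError(ValueError):
    """All bottom-phase signals identical: the slope is unidentifiable."""


class NonPhysicalKError(ValueError):
    """The fitted slope is not positive, which no partition coefficient is."""


class ReproducibilityWarning(UserWarning):
    """Replicate K estimates spread beyond the reproducibility tolerance."""


@dataclass(frozen=True)
class DilutionSeries:
    """Paired (bottom, top) phase signals over a dilution series.

    ``blank``, when given, is a (bottom, top) background pair subtracted
    from every point before fitting.
    """

    points: tuple[tuple[float, float], ...]
    blank: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple((float(b), float(t)) for b, t in self.points))
        if len(self.points) < 3:
            raise ValueError("a dilution series needs at least 3 points")
        bottoms = {b for b, _ in self.points}
        if len(bottoms) < 2:
            raise DegenerateDesignError(
                "all bottom-phase signals are equal; slope is unidentifiable"
            )

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        b = np.array([p[0] for p in self.points], dtype=float)
        t = np.array([p[1] for p in self.points], dtype=float)
        if self.blank is not None:
            b = b - self.blank[0]
            t = t - self.blank[1]
        return b, t


class KEstimate(NamedTuple):
    """A fitted partition coefficient: slope, its SE, n and intercept."""

    k: float
    se: float
    n_points: int
    intercept: float


class KAverage(NamedTuple):
    """Replicate-averaged K with the largest relative deviation."""

    k_mean: float
    max_rel_dev: float
    flagged: bool


def estimate_k(series: DilutionSeries, force_zero_intercept: bool = False) -> KEstimate:
    """Estimate K as the least-squares slope of top on bottom signal.

    Parameters
    ----------
    series
        The dilution series (blank-corrected internally when a blank is set).
    force_zero_intercept
        Fit ``top = K * bottom`` through the origin instead of
        ``top = a + K * bottom``.

    Raises
    ------
    NonPhysicalKError
        If the fitted slope is not strictly positive.
    """
    b, t = series.arrays()
    n = len(b)
    if force_zero_intercept:
        sxx = float(b @ b)
        k = float(b @ t) / sxx
        resid = t - k * b
        dof = n - 1
        se = math.sqrt(float(resid @ resid) / dof / sxx) if dof > 0 else 0.0
        intercept = 0.0
    else:
        x = np.column_stack([np.ones(n), b])
        beta, *_ = np.linalg.lstsq(x, t, rcond=None)
        intercept, k = float(beta[0]), float(beta[1])
        resid = t - x @ beta
        dof = n - 2
        sxx = float(np.sum((b - b.mean()) ** 2))
        se = math.sqrt(float(resid @ resid) / dof / sxx) if dof > 0 else 0.0
    if not k > 0:
        raise NonPhysicalKError(f"fitted slope {k:.4g} is not positive")
    return KEstimate(k=k, se=se, n_points=n, intercept=intercept)


def average_k(estimates: Sequence[KEstimate | float]) -> KAverage:
    """Average replicate K estimates and report their largest relative spread.

    Accepts :class:`KEstimate` objects or bare K values.  A
    :class:`ReproducibilityWarning` is issued (and ``flagged`` set) when the
    maximum relative deviation from the mean exceeds
    :data:`REPRODUCIBILITY_TOLERANCE`.
    """
    ks = [e.k if isinstance(e, KEstimate) else float(e) for e in estimates]
    if len(ks) < 2:
        raise ValueError("need at least two replicate estimates to average")
    mean = float(np.mean(ks))
    max_rel_dev = float(max(abs(k - mean) for k in ks) / mean)
    flagged = max_rel_dev > REPRODUCIBILITY_TOLERANCE
    if flagged:
        warnings.warn(
            f"replicate K values deviate by {max_rel_dev:.1%} from the mean "
            f"(tolerance {REPRODUCIBILITY_TOLERANCE:.0%})",
            ReproducibilityWarning,
            stacklevel=2,
        )
    return KAverage(k_mean=mean, max_rel_dev=max_rel_dev, flagged=flagged)
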