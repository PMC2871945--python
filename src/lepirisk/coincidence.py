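"""Temporal coincidence between larval development and maize pollen shed.

Larvae do not enter the susceptible instar synchronously, and crop plants do
not shed pollen synchronously: each process is summarised by a bivariate
distribution of (start day, end day), assumed bivariate normal, whose 95th
percentile region is an ellipse.  The coincidence parameter ``a`` is the
proportion of the larval-instar ellipse that is overlapped by the pollen-shed
ellipse: full overlap gives a = 1 (complete coincidence, no reduction in
exposure), disjoint ellipses give a = 0.  Downstream, realistic mortality is
the worst-case mortality multiplied by a (and by the physical-effects
proportion x).

Note the multiplier convention: ``a`` is the *retained* (overlapped)
fraction, so that perfect phenological coincidence leaves mortality
unreduced.  Regional values of ``a`` may also be supplied directly as
scalars; the ellipse machinery is the generative route when phenology
distributions are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

__all__ = ["PhenologyEllipse", "ellipse_area", "coincidence_retained"]


@dataclass(frozen=True)
class PhenologyEllipse:
    """Coverage ellipse of a bivariate-normal (start day, end day) distribution.

    Parameters
    ----------
    mean : array-like, shape (2,)
        Mean (start day-of-year, end day-of-year).
    cov : array-like, shape (2, 2)
        Covariance matrix in days^2; must be symmetric positive definite.
    coverage : float
        Probability mass enclosed; the region is
        {z : (z - mean)' inv(cov) (z - mean) <= chi2_2.ppf(coverage)}.
    """

    mean: np.ndarray
    cov: np.ndarray
    coverage: float = 0.95

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).reshape(2)
        cov = np.asarray(self.cov, dtype=float).reshape(2, 2)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if not 0 < self.coverage < 1:
            raise ValueError(f"coverage must be in (0, 1), got {self.coverage}")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError("covariance must be positive definite") from None

    @property
    def quantile(self) -> float:
        """Chi-square(2 df) quantile at the coverage level."""
        return float(chi2.ppf(self.coverage, df=2))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of which (n, 2) points fall inside the ellipse."""
        diff = np.atleast_2d(points) - self.mean
        sol = np.linalg.solve(self.cov, diff.T)
        maha = np.einsum("ij,ji->i", diff, sol)
        return maha <= self.quantile


def ellipse_area(e: PhenologyEllipse) -> float:
    """Area of the coverage ellipse in days^2: pi * q * sqrt(det cov)."""
    return float(np.pi * e.quantile * np.sqrt(np.linalg.det(e.cov)))


def coincidence_retained(
    larval: PhenologyEllipse,
    pollen: PhenologyEllipse,
    resolution: int = 500,
) -> float:
    """Proportion of the larval ellipse overlapped by the pollen ellipse.

    Computed on a deterministic ``resolution x resolution`` grid over the
    larval ellipse's bounding box: the fraction of grid points inside the
    larval ellipse that are also inside the pollen ellipse.  This is the
    temporal-coincidence multiplier ``a`` in [0, 1].

    ``resolution`` below 50 is rejected (the grid would be too coarse for
    the result to be meaningful at reporting precision).
    """
    if resolution < 50:
        raise ValueError(f"resolution must be >= 50 grid cells per axis, got {resolution}")
    # bounding box of the larval ellipse: mean +/- sqrt(q * diag(cov))
    half = np.sqrt(larval.quantile * np.diag(larval.cov))
    xs = np.linspace(larval.mean[0] - half[0], larval.mean[0] + half[0], resolution)
    ys = np.linspace(larval.mean[1] - half[1], larval.mean[1] + half[1], resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    in_larval = larval.contains(pts)
    n_larval = int(in_larval.sum())
    if n_larval == 0:  # degenerate: box collapsed to the boundary
        return 0.0
    in_both = pollen.contains(pts[in_larval])
    return float(in_both.sum() / n_larval)
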