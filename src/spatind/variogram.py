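"""Indicator variography: c80 cut-off, empirical variogram, spherical fit.

The geometry of the high-density patches that carry most of a stock's
abundance is characterized by thresholding the density field at the cut-off
``c80`` capturing 80% of total biomass, and modelling the omnidirectional
semivariogram of the resulting binary field with a nugget + spherical model.
The fitted range approximates the mean patch diameter; the normalized nugget
(percentage of total sill) measures small-scale roughness.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize_scalar, nnls
from scipy.spatial.distance import pdist

__all__ = [
    "AbundanceCutoff",
    "EmpiricalVariogram",
    "VariogramFit",
    "DegenerateVariogramError",
    "abundance_cutoff",
    "indicator_transform",
    "empirical_variogram",
    "fit_spherical_model",
    "spherical_variogram",
    "indicator_variography",
]


class DegenerateVariogramError(ValueError):
    """No spatial structure to fit (e.g. constant indicator field)."""


# ---------------------------------------------------------------------------
# cut-off and indicator transform
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AbundanceCutoff:
    """Density threshold whose exceedance set carries >= `fraction` of biomass."""

    c80: float                # t/nmi^2
    k: int                    # rank (1-based) of the last sample included
    captured_fraction: float  # abundance share of {z >= c80}
    comparison: str = "ge"


def abundance_cutoff(z, s, fraction: float = 0.80) -> AbundanceCutoff:
    """Smallest density whose exceedance set holds >= ``fraction`` of biomass.

    Samples are ranked by decreasing density and abundance ``z * s`` is
    cumulated; the cut-off is the density of the first rank at which the
    cumulative share reaches ``fraction``.  Because the cut-off equals an
    observed density, downstream membership uses ``z >= c80`` — a strict
    inequality would drop the defining sample and capture less than the
    target share.
    """
    z = np.asarray(z, dtype=float)
    s = np.asarray(s, dtype=float)
    q = float((z * s).sum())
    if q <= 0:
        raise DegenerateVariogramError("cut-off undefined: total abundance is zero")
    order = np.argsort(-z, kind="stable")
    cum = np.cumsum(z[order] * s[order])
    k = int(np.searchsorted(cum, fraction * q - 1e-12 * q) + 1)
    k = min(k, len(z))
    return AbundanceCutoff(c80=float(z[order[k - 1]]), k=k,
                           captured_fraction=float(cum[k - 1] / q))


def indicator_transform(z, cutoff: AbundanceCutoff | float,
                        strict: bool = False) -> tuple[np.ndarray, float]:
    """Binary exceedance field I = 1{z >= c} (or > c when ``strict``).

    Returns the indicator array and the proportion of ones.
    """
    z = np.asarray(z, dtype=float)
    c = cutoff.c80 if isinstance(cutoff, AbundanceCutoff) else float(cutoff)
    ind = (z > c) if strict else (z >= c)
    ind = ind.astype(float)
    return ind, float(ind.mean())


# ---------------------------------------------------------------------------
# empirical variogram
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EmpiricalVariogram:
    lag_centres: np.ndarray   # nmi, strictly increasing
    semivariance: np.ndarray  # NaN where a bin holds no pairs
    pair_counts: np.ndarray
    lag_width: float
    max_lag: float

    def nonempty(self) -> "EmpiricalVariogram":
        m = self.pair_counts > 0
        return EmpiricalVariogram(self.lag_centres[m], self.semivariance[m],
                                  self.pair_counts[m], self.lag_width, self.max_lag)


def empirical_variogram(x, y, values, lag_width: float = 1.0,
                        max_lag: float | None = None) -> EmpiricalVariogram:
    """Omnidirectional empirical semivariogram of a point-supported field.

    gamma(h) = (1 / 2N(h)) * sum over unordered pairs in the lag bin of
    (v_i - v_j)^2, binned by distance only; bin centres sit at multiples of
    ``lag_width`` (bin ``[h - w/2, h + w/2)``).  ``max_lag`` defaults to
    half the maximum inter-sample distance.  Pairs are unweighted: areas of
    influence weight the indicators themselves, not the pair counts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("variogram needs at least two samples")
    d = pdist(np.column_stack([x, y]))
    if max_lag is None:
        max_lag = float(d.max()) / 2.0
    sq = pdist(v[:, None], metric="sqeuclidean")
    bins = np.floor(d / lag_width + 0.5).astype(int)
    nbin = int(np.floor(max_lag / lag_width + 0.5)) + 1
    keep = bins < nbin
    counts = np.bincount(bins[keep], minlength=nbin)
    sums = np.bincount(bins[keep], weights=sq[keep], minlength=nbin)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = sums / (2.0 * counts)
    gamma[counts == 0] = np.nan
    centres = np.arange(nbin) * lag_width
    return EmpiricalVariogram(centres, gamma, counts, lag_width, float(max_lag))


# ---------------------------------------------------------------------------
# spherical model fit
# ---------------------------------------------------------------------------

def spherical_variogram(h, nugget: float, partial_sill: float, range_nmi: float) -> np.ndarray:
    """Nugget + spherical model: c0 + c1*(1.5 h/a - 0.5 (h/a)^3), flat beyond a.

    By convention the model is 0 at h = 0 (the nugget is the limit from the
    right); the discrete lag-0 bin of an empirical variogram compares
    co-located pairs and is fitted like any other bin.
    """
    h = np.asarray(h, dtype=float)
    r = np.minimum(h / range_nmi, 1.0)
    g = nugget + partial_sill * (1.5 * r - 0.5 * r ** 3)
    return np.where(h == 0.0, 0.0, g)


@dataclasses.dataclass
class VariogramFit:
    nugget: float         # c0 >= 0
    partial_sill: float   # c1 >= 0
    range_nmi: float      # a > 0
    objective: float      # pair-count-weighted SSE
    degenerate: bool = False

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def nugget_pct(self) -> float:
        """Nugget as a percentage of the total sill (small-scale roughness)."""
        if self.sill <= 0:
            return 100.0
        return 100.0 * self.nugget / self.sill

    def __call__(self, h) -> np.ndarray:
        return spherical_variogram(h, self.nugget, self.partial_sill, self.range_nmi)


def _nnls_at_range(h, gamma, w, a):
    """Weighted non-negative LS for (c0, c1) at fixed range a; returns (c0, c1, sse)."""
    r = np.minimum(h / a, 1.0)
    basis = np.where(h == 0.0, 0.0, 1.5 * r - 0.5 * r ** 3)
    ones = np.where(h == 0.0, 0.0, 1.0)
    A = np.column_stack([ones, basis]) * w[:, None]
    b = gamma * w
    coef, res = nnls(A, b)
    return float(coef[0]), float(coef[1]), float(res ** 2)


def fit_spherical_model(empirical: EmpiricalVariogram) -> VariogramFit:
    """Fit nugget + spherical by pair-count-weighted least squares.

    The range is found by a grid search at ``lag_width / 2`` resolution
    followed by bounded scalar refinement; at every candidate range the
    nugget and partial sill solve a non-negative linear least-squares
    problem weighted by pair counts.  Deterministic and derivative-free, so
    it is robust to the non-smooth dependence of the spherical basis on the
    range.
    """
    emp = empirical.nonempty()
    h, gamma, counts = emp.lag_centres, emp.semivariance, emp.pair_counts.astype(float)
    if len(h) < 3:
        raise DegenerateVariogramError("need >= 3 non-empty lag bins to fit")
    if np.all(gamma == 0):
        raise DegenerateVariogramError("all semivariances are zero: no structure to fit")
    w = np.sqrt(counts)
    step = emp.lag_width / 2.0
    grid = np.arange(step, emp.max_lag + step / 2.0, step)
    sses = np.array([_nnls_at_range(h, gamma, w, a)[2] for a in grid])
    i = int(np.argmin(sses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(lambda a: _nnls_at_range(h, gamma, w, a)[2],
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        a_best = float(res.x) if res.fun <= sses[i] else float(grid[i])
    else:
        a_best = float(grid[i])
    c0, c1, sse = _nnls_at_range(h, gamma, w, a_best)
    degenerate = (c0 + c1) <= 0 or c1 <= 1e-12 * max(c0, 1.0)
    return VariogramFit(nugget=c0, partial_sill=c1, range_nmi=a_best,
                        objective=sse, degenerate=degenerate)


# ---------------------------------------------------------------------------
# one-call pipeline for a survey slice
# ---------------------------------------------------------------------------

def indicator_variography(x, y, z, s, fraction: float = 0.80,
                          lag_width: float = 1.0,
                          max_lag: float | None = None) -> dict:
    """c80 -> indicator -> empirical variogram -> spherical fit for one slice.

    Returns a dict with the cut-off, proportion of ones, the empirical
    variogram and the fit (range in nmi, normalized nugget in percent).
    """
    cut = abundance_cutoff(z, s, fraction)
    ind, p = indicator_transform(z, cut)
    emp = empirical_variogram(x, y, ind, lag_width=lag_width, max_lag=max_lag)
    fit = fit_spherical_model(emp)
    return {"cutoff": cut, "proportion": p, "empirical": emp, "fit": fit,
            "range_nmi": fit.range_nmi, "nugget_pct": fit.nugget_pct}
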