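"""Independent brute-force reference implementations.

Deliberately naive: plain Python loops, no vectorization, no incremental
updates, no code shared with the package.  Used to cross-check every
indicator on small random instances.
"""

from __future__ import annotations

import math


def cg_naive(x, y, z, s):
    num_x = num_y = den = 0.0
    for xi, yi, zi, si in zip(x, y, z, s):
        num_x += zi * si * xi
        num_y += zi * si * yi
        den += zi * si
    return num_x / den, num_y / den


def inertia_naive(x, y, z, s):
    cgx, cgy = cg_naive(x, y, z, s)
    num = den = 0.0
    for xi, yi, zi, si in zip(x, y, z, s):
        num += zi * si * ((xi - cgx) ** 2 + (yi - cgy) ** 2)
        den += zi * si
    return num / den


def isotropy_naive(x, y, z, s):
    cgx, cgy = cg_naive(x, y, z, s)
    sxx = sxy = syy = den = 0.0
    for xi, yi, zi, si in zip(x, y, z, s):
        w = zi * si
        sxx += w * (xi - cgx) ** 2
        sxy += w * (xi - cgx) * (yi - cgy)
        syy += w * (yi - cgy) ** 2
        den += w
    sxx, sxy, syy = sxx / den, sxy / den, syy / den
    # eigenvalues of the 2x2 symmetric covariance by the quadratic formula
    tr, det = sxx + syy, sxx * syy - sxy * sxy
    disc = math.sqrt(max(tr * tr / 4 - det, 0.0))
    l1, l2 = tr / 2 + disc, max(tr / 2 - disc, 0.0)
    if l1 <= 0:
        return 1.0
    if l2 < 1e-12 * l1:  # collinear up to rounding noise
        return 0.0
    return math.sqrt(l2 / l1)


def pa_naive(z, s):
    return sum(si for zi, si in zip(z, s) if zi > 0)


def _ranked(z, s):
    """(z, s) pairs sorted by decreasing density, ties keeping input order."""
    return [pair[2:] for pair in sorted(
        ((-zi, i, zi, si) for i, (zi, si) in enumerate(zip(z, s))))]


def sa_naive(z, s):
    q = sum(zi * si for zi, si in zip(z, s))
    total = 0.0
    cum = 0.0
    for zi, si in _ranked(z, s):
        cum += zi * si
        total += si * (q - cum + zi * si / 2.0)
    return 2.0 * total / q


def ea_naive(z, s):
    q = sum(zi * si for zi, si in zip(z, s))
    return q * q / sum(zi * zi * si for zi, si in zip(z, s))


def gic_naive(pop1, pop2):
    cg1, cg2 = cg_naive(*pop1), cg_naive(*pop2)
    i1, i2 = inertia_naive(*pop1), inertia_naive(*pop2)
    d2 = (cg1[0] - cg2[0]) ** 2 + (cg1[1] - cg2[1]) ** 2
    if d2 + i1 + i2 == 0:
        return 1.0
    return 1.0 - d2 / (d2 + i1 + i2)


def c80_naive(z, s, fraction=0.80):
    q = sum(zi * si for zi, si in zip(z, s))
    cum = 0.0
    for zi, si in _ranked(z, s):
        cum += zi * si
        if cum >= fraction * q - 1e-12 * q:
            return zi
    return _ranked(z, s)[-1][0]


def patches_naive(x, y, z, s, dlim=20.0):
    """Sequential patch assignment; centres recomputed from scratch each join.

    Returns a list of member-index lists, in patch creation order.
    """
    order = [i for _, i in sorted((-z[i], i) for i in range(len(z)) if z[i] > 0)]
    patches: list[list[int]] = []

    def centre(members):
        wx = wy = w = 0.0
        for i in members:
            wi = z[i] * s[i]
            wx += wi * x[i]
            wy += wi * y[i]
            w += wi
        return wx / w, wy / w

    for i in order:
        best, best_d = None, None
        for j, members in enumerate(patches):
            cx, cy = centre(members)
            d = math.hypot(x[i] - cx, y[i] - cy)
            if best_d is None or d < best_d:
                best, best_d = j, d
        if best is not None and best_d <= dlim:
            patches[best].append(i)
        else:
            patches.append([i])
    return patches


def variogram_naive(x, y, v, lag_width=1.0, max_lag=None):
    """All-pairs loop semivariogram; returns {bin_centre: (gamma, count)}."""
    n = len(x)
    dmax = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dmax = max(dmax, math.hypot(x[i] - x[j], y[i] - y[j]))
    if max_lag is None:
        max_lag = dmax / 2.0
    nbin = int(math.floor(max_lag / lag_width + 0.5)) + 1
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = math.hypot(x[i] - x[j], y[i] - y[j])
            b = int(math.floor(d / lag_width + 0.5))
            if b < nbin:
                sums[b] = sums.get(b, 0.0) + (v[i] - v[j]) ** 2
                counts[b] = counts.get(b, 0) + 1
    return {b * lag_width: (sums[b] / (2 * counts[b]), counts[b]) for b in sums}
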