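"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's sampling code: the ray-march
oracle steps at a fixed small interval with its own nearest/linear
lookup, and the percentile oracle interpolates order statistics by hand.
"""

from __future__ import annotations

import numpy as np


def ray_march_line_integral(volume, src, direction, step_mm=0.1, t_max=3000.0):
    """Fixed-step ray march of the trilinear interpolant of ``volume``.

    ``volume`` is a fluorovol Volume3D; ``src``/``direction`` in world mm
    (direction need not be normalized).  Out-of-grid samples contribute 0.
    """
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    t = np.arange(0.0, t_max, step_mm) + 0.5 * step_mm
    pts = np.asarray(src, float)[None, :] + t[:, None] * d[None, :]
    idx = (pts - volume.origin_mm) / volume.spacing_mm
    total = 0.0
    nx, ny, nz = volume.shape
    v = volume.voxels
    for x, y, z in idx:
        i0, j0, k0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
        fx, fy, fz = x - i0, y - j0, z - k0
        acc = 0.0
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    ii, jj, kk = i0 + di, j0 + dj, k0 + dk
                    if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                        w = (fx if di else 1 - fx) * (fy if dj else 1 - fy) * (fz if dk else 1 - fz)
                        acc += w * v[ii, jj, kk]
        total += acc
    return total * step_mm


def percentile_linear(values, q):
    """Linear-interpolated inclusive percentile of |values| by hand."""
    a = np.sort(np.abs(np.asarray(values, float)))
    if a.size == 1:
        return float(a[0])
    pos = (q / 100.0) * (a.size - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, a.size - 1)
    frac = pos - lo
    return float(a[lo] * (1 - frac) + a[hi] * frac)


def brute_force_lambda(rendered, x, grid=None):
    """1-D scan + refinement for min_l ||rendered - l x||^2."""
    r = np.asarray(rendered, float).ravel()
    xx = np.asarray(x, float).ravel()
    lams = np.linspace(-10, 10, 20001)
    costs = [np.sum((r - l * xx) ** 2) for l in lams]
    k = int(np.argmin(costs))
    lo, hi = lams[max(k - 1, 0)], lams[min(k + 1, lams.size - 1)]
    fine = np.linspace(lo, hi, 20001)
    costs = [np.sum((r - l * xx) ** 2) for l in fine]
    return float(fine[int(np.argmin(costs))])
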