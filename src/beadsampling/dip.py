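"""Hartigan's dip statistic for unimodality.

The dip of a sample is the largest deviation between its empirical
distribution function and the closest unimodal distribution function:
``D = min over unimodal G of sup_t |F_n(t) - G(t)|``.  It is computed by
the classical greatest-convex-minorant / least-concave-majorant iteration:
within a shrinking candidate modal interval, fit the GCM to the lower
corners of the ecdf steps and the LCM to the upper corners, find the
largest gap between the two envelopes, and account for the flank
deviations of the ecdf outside the modal interval.  The statistic is
always at least ``1/(2n)`` (the unavoidable half-jump mismatch).

Ties in the data are supported only approximately (the envelope
interpolation treats coincident points as a near-vertical segment);
decision-time data and bootstrap draws are continuous, where the
computation is exact.
"""

from __future__ import annotations

import numpy as np


def _lower_hull(t: np.ndarray, a: np.ndarray) -> list[int]:
    """Indices of the lower convex hull (greatest convex minorant) touches."""
    hull: list[int] = []
    for i in range(t.size):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            # drop i1 if it lies on or above segment i0 -> i
            if (t[i] - t[i0]) * (a[i1] - a[i0]) >= (t[i1] - t[i0]) * (
                a[i] - a[i0]
            ):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _upper_hull(t: np.ndarray, a: np.ndarray) -> list[int]:
    """Indices of the upper concave hull (least concave majorant) touches."""
    hull: list[int] = []
    for i in range(t.size):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            if (t[i] - t[i0]) * (a[i1] - a[i0]) <= (t[i1] - t[i0]) * (
                a[i] - a[i0]
            ):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _interp(t: np.ndarray, touches: list[int], a: np.ndarray) -> np.ndarray:
    """Envelope value at every t, linearly interpolated between touches."""
    tx = t[touches]
    ax = a[touches]
    return np.interp(t, tx, ax)


def dip_statistic(samples: np.ndarray) -> float:
    """Hartigan's dip statistic of a 1-D sample."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0

    low, high = 0, n - 1
    best = 1.0  # count units; the final dip is best / (2n)

    while True:
        t = x[low : high + 1]
        lo_corners = np.arange(low, high + 1, dtype=float)  # F(x_i^-) * n
        hi_corners = lo_corners + 1.0  # F(x_i) * n
        gcm = _lower_hull(t, lo_corners)
        lcm = _upper_hull(t, hi_corners)
        gcm_vals = _interp(t, gcm, lo_corners)
        lcm_vals = _interp(t, lcm, hi_corners)

        # largest gap between the envelopes, tracked with the touch points
        # bracketing it (they define the next candidate modal interval)
        d = -np.inf
        new_low, new_high = low, high
        lcm_arr = np.array(lcm)
        gcm_arr = np.array(gcm)
        for gi in gcm:
            gap = lcm_vals[gi] - lo_corners[gi]
            if gap > d:
                d = gap
                right = lcm_arr[lcm_arr >= gi]
                new_low = low + gi
                new_high = low + int(right[0] if right.size else gi)
        for li in lcm:
            gap = hi_corners[li] - gcm_vals[li]
            if gap > d:
                d = gap
                left = gcm_arr[gcm_arr <= li]
                new_low = low + int(left[-1] if left.size else li)
                new_high = low + li

        if d <= best:
            break

        # flank deviations of the ecdf outside the new modal interval
        kl = new_low - low  # local index of new_low
        ku = new_high - low
        dl = float(np.max(hi_corners[: kl + 1] - gcm_vals[: kl + 1]))
        du = float(np.max(lcm_vals[ku:] - lo_corners[ku:]))
        best = max(best, dl, du)

        if (new_low, new_high) == (low, high) or new_high - new_low <= 1:
            break
        low, high = new_low, new_high

    return best / (2.0 * n)


def dip_pvalue(
    samples: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """(dip, bootstrap p) against the uniform unimodal null.

    The null distribution of the dip is simulated by drawing ``n_boot``
    uniform samples of the same size (the asymptotically least favorable
    unimodal case); ``p = (1 + #{D_null >= D_obs}) / (n_boot + 1)``.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 4:
        raise ValueError("dip test needs at least 4 observations")
    rng = np.random.default_rng(rng)
    d_obs = dip_statistic(x)
    exceed = 0
    for _ in range(n_boot):
        if dip_statistic(rng.uniform(size=x.size)) >= d_obs:
            exceed += 1
    return d_obs, (1.0 + exceed) / (n_boot + 1.0)
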