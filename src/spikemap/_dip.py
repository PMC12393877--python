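"""Hartigan & Hartigan's dip statistic of unimodality.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and the class of unimodal distribution functions.  It is
computed by the classical greatest-convex-minorant / least-concave-majorant
cycling algorithm (the same algorithm behind the reference Fortran/C
implementations).  The statistic lies in [1/(2n), 1/4]: evenly spread data
attain the lower bound, two equal point masses the upper.

The p-value is calibrated by bootstrap against the U(0,1) null, the
asymptotically least favorable unimodal distribution.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_pvalue"]


def dip_statistic(x: np.ndarray) -> float:
    """Dip statistic of a 1-D sample.

    Parameters
    ----------
    x:
        Sample values; at least 4 observations are required.
    """
    xs = np.sort(np.asarray(x, dtype=np.float64).ravel())
    n = xs.size
    if n < 4:
        raise ValueError("dip statistic needs at least 4 observations")
    if xs[0] == xs[-1]:
        return 0.0

    # 1-based arrays to mirror the published algorithm
    X = np.empty(n + 1)
    X[1:] = xs
    mn = np.empty(n + 1, dtype=np.int64)
    mj = np.empty(n + 1, dtype=np.int64)

    # indices over which combination is needed for the convex minorant (GCM)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (X[j] - X[mnj]) * (mnj - mnmnj) < (X[mnj] - X[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj

    # ... and for the concave majorant (LCM)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (X[k] - X[mjk]) * (mjk - mjmjk) < (X[mjk] - X[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # in units of counts; divided by 2n at the end
    gcm = np.empty(n + 2, dtype=np.int64)
    lcm = np.empty(n + 2, dtype=np.int64)

    while True:
        # change points of the GCM from high to low, and of the LCM upward
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i
        ix = ig - 1

        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i
        iv = 2

        # largest distance between the GCM and the LCM over [low, high]
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (X[lcmiv] - X[gcmi1]) * (gcmix - gcmi1) / (
                        X[gcmix] - X[gcmi1]
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (X[gcmix] - X[lcmiv1]) * (lcmiv - lcmiv1) / (
                        X[lcmiv] - X[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # dip within the convex-minorant fit
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and X[je] != X[jb]:
                C = (je - jb) / (X[je] - X[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (X[jj] - X[jb]) * C
                    if t > max_t:
                        max_t = t
            if max_t > dip_l:
                dip_l = max_t

        # dip within the concave-majorant fit
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and X[je] != X[jb]:
                C = (je - jb) / (X[je] - X[jb])
                for jj in range(jb, je + 1):
                    t = (X[jj] - X[jb]) * C - (jj - jb - 1)
                    if t > max_t:
                        max_t = t
            if max_t > dip_u:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dipnew > dip:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = int(gcm[ig])
        high = int(lcm[ih])

    return dip / (2.0 * n)


def dip_pvalue(
    x: np.ndarray, n_boot: int = 1000, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value against the uniform null.

    ``p = (1 + #{dip_boot >= dip_obs}) / (n_boot + 1)``; small p rejects
    unimodality (e.g. bimodal inter-spike-interval distributions of bursting
    neurons).
    """
    rng = rng if rng is not None else np.random.default_rng()
    x = np.asarray(x, dtype=np.float64).ravel()
    d = dip_statistic(x)
    n = x.size
    boots = np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])
    p = (1.0 + float((boots >= d).sum())) / (n_boot + 1.0)
    return d, p
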