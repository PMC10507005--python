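"""Independent reference implementations used only to cross-check the
package: a naive six-nested-loop formula enumerator, a straight-line
re-implementation of the compound-category thresholds, and closed-form
simple-regression formulas. These deliberately share no code with the
implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _stats

# independent copy of the isotope masses (IUPAC values, re-entered by hand)
_M = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
}


def brute_force_candidates(
    neutral_mass: float,
    tol_ppm: float,
    bounds: dict[str, tuple[int, int]],
) -> set[tuple[int, int, int, int, int, int]]:
    """Exhaustive six-nested-loop enumeration under the same screens."""
    tol = neutral_mass * tol_ppm * 1e-6
    out = set()
    for n in range(bounds["N"][0], bounds["N"][1] + 1):
        for s in range(bounds["S"][0], bounds["S"][1] + 1):
            for p in range(bounds["P"][0], bounds["P"][1] + 1):
                for o in range(bounds["O"][0], bounds["O"][1] + 1):
                    for c in range(max(1, bounds["C"][0]), bounds["C"][1] + 1):
                        base = n * _M["N"] + s * _M["S"] + p * _M["P"] + o * _M["O"] + c * _M["C"]
                        if base > neutral_mass + tol:
                            break
                        for h in range(bounds["H"][0], bounds["H"][1] + 1):
                            mass = base + h * _M["H"]
                            if mass > neutral_mass + tol:
                                break
                            if mass < neutral_mass - tol:
                                continue
                            # screens
                            if (h - n - p) % 2 != 0:
                                continue
                            dbe = 1 + c - h / 2 + (n + p) / 2
                            if dbe < 0:
                                continue
                            saturated = h == 2 * c + 2 + n + p
                            if not saturated and not (0.3 * c <= h <= 2.5 * c):
                                continue
                            if saturated and h < 0.3 * c:
                                continue
                            if o > 1.2 * c:
                                continue
                            out.add((c, h, n, o, s, p))
    return out


def classify_reference(c: int, h: int, n: int, o: int, s: int, p: int) -> str:
    """Straight-line re-implementation of the category threshold table."""
    dbe = 1 + c - h / 2 + (n + p) / 2
    denom = c - 0.5 * o - n - s - p
    if denom <= 0:
        ai = 0.0
    else:
        ai = (1 + c - 0.5 * o - s - 0.5 * (n + p + h)) / denom
        if ai < 0:
            ai = 0.0
    hc = h / c
    rich = "Or" if o / c > 0.5 else "Op"
    if dbe == 0:
        return "Sat_" + rich
    if ai >= 0.5:
        return "A_" + rich
    if 1.5 <= hc <= 2.0:
        return "Un_withN" if n > 0 else "Un_" + rich
    if hc < 1.5:
        return "HUn_" + rich
    return "Sat_" + rich


def ols_reference(x: np.ndarray, y: np.ndarray) -> dict:
    """Simple regression via the normal equations, with the slope t-test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    sxy = np.sum((x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    ss_res = np.sum(resid**2)
    ss_tot = np.sum((y - ybar) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    se = np.sqrt(ss_res / (n - 2) / sxx)
    t = slope / se
    p = 2.0 * _stats.t.sf(abs(t), n - 2)
    return {"slope": slope, "intercept": intercept, "r2": r2, "p": p}
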