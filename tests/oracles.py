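"""Independent brute-force oracles used to cross-check the implementation.

Every function here is deliberately naive — dense sampling, explicit
risk tables, O(n^2) pair enumeration, closed-form formulas — and shares
no code path with the package.
"""

from __future__ import annotations

import numpy as np


def bilinear(img: np.ndarray, r: float, c: float) -> float:
    """Manual bilinear interpolation with zero padding outside the grid."""
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    fr, fc = r - r0, c - c0
    total = 0.0
    for dr, wr in ((0, 1 - fr), (1, fr)):
        for dc, wc in ((0, 1 - fc), (1, fc)):
            rr, cc = r0 + dr, c0 + dc
            if 0 <= rr < img.shape[0] and 0 <= cc < img.shape[1]:
                total += wr * wc * img[rr, cc]
    return total


def ray_profile_oracle(
    sl: np.ndarray,
    center: tuple[float, float],
    angle_deg: float,
    voxel_rc: tuple[float, float],
    step_mm: float = 0.05,
) -> float:
    """Max count along one ray by dense marching with manual bilinear."""
    vr, vc = voxel_rc
    theta = np.deg2rad(angle_deg)
    u_row, u_col = -np.cos(theta), -np.sin(theta)
    max_radius = np.hypot(sl.shape[0] * vr, sl.shape[1] * vc)
    best = 0.0
    for radius in np.arange(0.0, max_radius, step_mm):
        r = center[0] + radius * u_row / vr
        c = center[1] + radius * u_col / vc
        best = max(best, bilinear(sl, r, c))
    return best


def km_oracle(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit estimator computed directly over risk sets."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    uniq = np.unique(times)
    surv = []
    s = 1.0
    for t in uniq:
        at_risk = (times >= t).sum()
        deaths = ((times == t) & events).sum()
        if at_risk > 0:
            s *= 1.0 - deaths / at_risk
        surv.append(s)
    return uniq, np.array(surv)


def logrank_oracle(ta, ea, tb, eb) -> float:
    """Two-group log-rank chi-square from an explicit risk table."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    all_t = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_t:
        n1 = (ta >= t).sum()
        n2 = (tb >= t).sum()
        d1 = ((ta == t) & ea).sum()
        d2 = ((tb == t) & eb).sum()
        n, d = n1 + n2, d1 + d2
        if n < 2 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return 0.0 if var == 0 else o_minus_e**2 / var


def auc_pair_count_oracle(scores, labels) -> float:
    """AUC by exhaustive positive/negative pair enumeration (ties = 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def chi2_2x2_oracle(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square on a 2x2 table via the closed-form identity."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return 0.0 if denom == 0 else n * (a * d - b * c) ** 2 / denom
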