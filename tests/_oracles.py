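"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (double loops, explicit
enumeration) and shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """All-pairs signed center-to-center distance map."""
    spacing = np.asarray(spacing, float)
    inside = np.argwhere(mask) * spacing
    outside = np.argwhere(~mask) * spacing
    out = np.empty(mask.shape)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * spacing
        if mask[idx]:
            out[idx] = -np.sqrt(((outside - p) ** 2).sum(1)).min()
        else:
            out[idx] = np.sqrt(((inside - p) ** 2).sum(1)).min()
    return out


def brute_zone(mask, brain, spacing, inner, outer, closed_inner=False):
    """Distance banding from the brute-force map (half-open (inner,outer]
    unless closed_inner, which gives the [inner, outer] straddling band)."""
    d = brute_signed_distance(mask, spacing)
    if closed_inner:
        zone = (d >= inner) & (d <= outer)
    else:
        zone = (d > inner) & (d <= outer)
    return zone & brain


def enumerate_runs(labels: np.ndarray, direction):
    """All maximal runs (gray level, length) along one direction, walking
    every start voxel explicitly; label 0 breaks runs."""
    labels = np.asarray(labels)
    d = np.asarray(direction)
    runs = []
    for start in np.ndindex(labels.shape):
        prev = np.asarray(start) - d
        # only start a run at the first voxel of a line segment
        if (
            (0 <= prev).all()
            and (prev < labels.shape).all()
            and labels[tuple(prev)] == labels[start]
            and labels[start] != 0
        ):
            continue
        if labels[start] == 0:
            continue
        g = labels[start]
        length = 1
        cur = np.asarray(start) + d
        while (0 <= cur).all() and (cur < labels.shape).all() and labels[tuple(cur)] == g:
            length += 1
            cur += d
        runs.append((int(g), int(length)))
    return runs


def glrlm_from_runs(runs, n_levels, n_voxels):
    """The 16 run-length features from an explicit run list."""
    if not runs:
        raise ValueError("no runs")
    max_len = max(l for _, l in runs)
    P = np.zeros((n_levels + 1, max_len + 1))
    for g, l in runs:
        P[g, l] += 1
    Ns = P.sum()
    out = {}
    sre = lre = gln = rln = lglre = hglre = 0.0
    srlgle = srhgle = lrlgle = lrhgle = 0.0
    for g in range(1, n_levels + 1):
        for l in range(1, max_len + 1):
            c = P[g, l]
            if c == 0:
                continue
            sre += c / l**2
            lre += c * l**2
            lglre += c / g**2
            hglre += c * g**2
            srlgle += c / (g**2 * l**2)
            srhgle += c * g**2 / l**2
            lrlgle += c * l**2 / g**2
            lrhgle += c * g**2 * l**2
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    gln = (row**2).sum()
    rln = (col**2).sum()
    p = P / Ns
    mu_g = sum(p[g, l] * g for g in range(P.shape[0]) for l in range(P.shape[1]))
    mu_l = sum(p[g, l] * l for g in range(P.shape[0]) for l in range(P.shape[1]))
    glv = sum(
        p[g, l] * (g - mu_g) ** 2 for g in range(P.shape[0]) for l in range(P.shape[1])
    )
    rlv = sum(
        p[g, l] * (l - mu_l) ** 2 for g in range(P.shape[0]) for l in range(P.shape[1])
    )
    re = -sum(
        p[g, l] * np.log2(p[g, l])
        for g in range(P.shape[0])
        for l in range(P.shape[1])
        if p[g, l] > 0
    )
    out["sre"] = sre / Ns
    out["lre"] = lre / Ns
    out["gln"] = gln / Ns
    out["glnn"] = gln / Ns**2
    out["rln"] = rln / Ns
    out["rlnn"] = rln / Ns**2
    out["rp"] = Ns / n_voxels
    out["glv"] = glv
    out["rlv"] = rlv
    out["re"] = re
    out["lglre"] = lglre / Ns
    out["hglre"] = hglre / Ns
    out["srlgle"] = srlgle / Ns
    out["srhgle"] = srhgle / Ns
    out["lrlgle"] = lrlgle / Ns
    out["lrhgle"] = lrhgle / Ns
    return out


def brute_max_diameters(mask: np.ndarray, spacing):
    """Max 3D and per-plane 2D pairwise voxel-center distances, by full
    pair enumeration over every mask voxel."""
    spacing = np.asarray(spacing, float)
    pts = np.argwhere(mask)
    mm = pts * spacing

    def pair_max(p):
        best = 0.0
        for i in range(len(p)):
            for j in range(i + 1, len(p)):
                best = max(best, float(np.sqrt(((p[i] - p[j]) ** 2).sum())))
        return best

    out = {"max_3d": pair_max(mm)}
    for plane, ax in (("axial", 2), ("coronal", 1), ("sagittal", 0)):
        keep = [a for a in range(3) if a != ax]
        best = 0.0
        for level in np.unique(pts[:, ax]):
            sl = mm[pts[:, ax] == level][:, keep]
            best = max(best, pair_max(sl))
        out[plane] = best
    return out


def hand_km(time, event):
    """Product-limit estimator evaluated by the textbook table."""
    times = sorted(set(time))
    s = 1.0
    curve = []
    for t in times:
        at_risk = sum(1 for x in time if x >= t)
        deaths = sum(1 for x, e in zip(time, event) if x == t and e == 1)
        if deaths:
            s *= 1 - deaths / at_risk
        curve.append((t, s))
    return curve


def brute_uno(time, event, risk, tau=None):
    """Uno's IPCW c-index by explicit double loop.

    G is the product-limit estimator of the censoring distribution with
    events removed from the risk set before censorings at the same time;
    the weight uses the left limit G(T_i-).
    """
    n = len(time)

    def G_left(t):
        s = 1.0
        for u in sorted(set(time)):
            if u >= t:
                break
            at_risk = sum(1 for x in time if x >= u)
            events_at_u = sum(1 for x, e in zip(time, event) if x == u and e == 1)
            cens_at_u = sum(1 for x, e in zip(time, event) if x == u and e == 0)
            if cens_at_u:
                s *= 1 - cens_at_u / (at_risk - events_at_u)
        return s

    num = den = 0.0
    for i in range(n):
        if event[i] != 1:
            continue
        if tau is not None and time[i] >= tau:
            continue
        w = 1.0 / G_left(time[i]) ** 2
        for j in range(n):
            if j == i:
                continue
            usable = time[i] < time[j] or (time[i] == time[j] and event[j] == 0)
            if not usable:
                continue
            den += w
            if risk[i] > risk[j]:
                num += w
            elif risk[i] == risk[j]:
                num += 0.5 * w
    return num / den


def hand_logrank(time, event, group):
    """Two-sample log-rank chi-square from the O−E/V table."""
    O = E = V = 0.0
    for t in sorted(set(t for t, e in zip(time, event) if e == 1)):
        n_at = sum(1 for x in time if x >= t)
        n1_at = sum(1 for x, g in zip(time, group) if x >= t and g)
        d = sum(1 for x, e in zip(time, event) if x == t and e == 1)
        d1 = sum(1 for x, e, g in zip(time, event, group) if x == t and e == 1 and g)
        O += d1
        E += d * n1_at / n_at
        if n_at > 1:
            V += d * (n1_at / n_at) * (1 - n1_at / n_at) * (n_at - d) / (n_at - 1)
    return (O - E) ** 2 / V if V > 0 else 0.0
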