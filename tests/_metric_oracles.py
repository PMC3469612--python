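"""Independent line-by-line transliterations of the quality measures.

Written directly from the operational definitions, sharing no code with
harmony_eeg.metrics: plain loops, explicit great-arc formulas, no helper
reuse.  Used only as test oracles.
"""

import math

import numpy as np


def _r_eff(surface):
    area = 0.0
    v = surface.folded.vertices
    for a, b, c in surface.folded.faces:
        area += 0.5 * np.linalg.norm(np.cross(v[b] - v[a], v[c] - v[a]))
    return math.sqrt(area / (4.0 * math.pi))


def _arc(u, w):
    return math.acos(max(-1.0, min(1.0, float(np.dot(u, w)))))


def oracle_localization_error(values, patch, space):
    surf = space.surface(patch.hemisphere)
    off = space.offsets[space.hemisphere_index(patch.hemisphere)]
    mags = [abs(values[off + j]) for j in range(surf.n_vertices)]
    r = _r_eff(surf)
    # true source location: unweighted centroid snapped to the mesh
    cen = np.zeros(3)
    for j in patch.vertices:
        cen += surf.sphere.vertices[j]
    cen /= np.linalg.norm(cen)
    best, best_dot = 0, -2.0
    for j in range(surf.n_vertices):
        d = float(np.dot(surf.sphere.vertices[j], cen))
        if d > best_dot:
            best, best_dot = j, d
    target = surf.sphere.vertices[best]
    n = len(patch.vertices)
    order = sorted(range(surf.n_vertices), key=lambda j: -mags[j])[:n]
    num = sum(mags[j] * _arc(surf.sphere.vertices[j], target) * r for j in order)
    den = sum(mags[j] for j in order)
    raw = num / den
    num_s = sum(abs(a) * _arc(surf.sphere.vertices[j], target) * r
                for j, a in zip(patch.vertices, patch.amplitudes))
    den_s = sum(abs(a) for a in patch.amplitudes)
    self_extent = num_s / den_s
    return max(raw - self_extent, 0.0)


def oracle_surface_bias(values, patches, space, head_center):
    pos = space.positions_folded()
    mags = np.abs(np.asarray(values, dtype=float))
    n_sel = sum(len(p.vertices) for p in patches)
    order = sorted(range(len(mags)), key=lambda j: -mags[j])[:n_sel]
    num = sum(mags[j] * np.linalg.norm(pos[j] - head_center) for j in order)
    d_sol = num / sum(mags[j] for j in order)
    num_s, den_s = 0.0, 0.0
    for p in patches:
        off = space.offsets[space.hemisphere_index(p.hemisphere)]
        for j, a in zip(p.vertices, p.amplitudes):
            num_s += abs(a) * np.linalg.norm(pos[off + j] - head_center)
            den_s += abs(a)
    d_src = num_s / den_s
    return (d_sol - d_src) / d_src


def oracle_widths(values, hemisphere, space, n_strongest):
    surf = space.surface(hemisphere)
    off = space.offsets[space.hemisphere_index(hemisphere)]
    mags = [abs(values[off + j]) for j in range(surf.n_vertices)]
    r = _r_eff(surf)

    def width(selected):
        cen = np.zeros(3)
        for j in selected:
            cen += mags[j] * surf.sphere.vertices[j]
        cen /= np.linalg.norm(cen)
        num = sum(mags[j] * _arc(surf.sphere.vertices[j], cen) * r for j in selected)
        return num / sum(mags[j] for j in selected)

    order = sorted(range(surf.n_vertices), key=lambda j: -mags[j])
    w_min = width(order[:n_strongest])
    half = [j for j in range(surf.n_vertices) if mags[j] > 0.5 * max(mags)]
    return w_min, width(half)


def oracle_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def oracle_auc_pairwise(source_vals, nonsource_vals):
    """All-pairs Mann-Whitney probability, ties counted one half."""
    wins = 0.0
    for s in source_vals:
        for t in nonsource_vals:
            if s > t:
                wins += 1.0
            elif s == t:
                wins += 0.5
    return wins / (len(source_vals) * len(nonsource_vals))
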