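"""Reconstruction-quality measures for simulated source configurations.

Six operational measures compare a distributed source estimate against the
simulated truth:

* localization error (LE, mm): amplitude-weighted great-arc distance of the
  strongest dipoles from the true source location, corrected for the
  source's own spatial extent;
* amplitude ratio (AR): reconstructed left/right source-strength ratio
  (truth = 2 in the standard two-source design);
* surface bias (SB): relative outward shift of the solution's
  centre-of-mass distance from the head centre;
* widths W_min / W_mid (mm): hotspot size and half-maximum spread of the
  solution about its own centre;
* coherence K_coh: true hotspot width over solution hotspot width (<= 1,
  1 = solution as tight as the source);
* congruency K_cong: Pearson correlation across configurations between
  W_mid and LE - how honestly the solution's spread signals its error;
* AUC: Mann-Whitney probability that a source-patch vertex out-ranks a
  same-hemisphere most-active non-source vertex.

All measures are invariant to global positive rescaling of the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .geometry import SourcePatch, SourceSpace, effective_radius

__all__ = [
    "MetricsReport",
    "localization_error",
    "amplitude_ratio",
    "surface_bias",
    "widths",
    "coherence",
    "congruency",
    "auc",
    "evaluate_configuration",
]


def _hemi_magnitudes(values: np.ndarray, space: SourceSpace, hemisphere: str) -> np.ndarray:
    sl = space.hemisphere_slice(hemisphere)
    return np.abs(np.asarray(values, dtype=float)[sl])


def _true_center_vertex(patch: SourcePatch, space: SourceSpace) -> int:
    """Unweighted centroid of the patch on the sphere, snapped to the mesh."""
    surf = space.surface(patch.hemisphere)
    mean = surf.sphere.vertices[patch.vertices].mean(axis=0)
    mean /= np.linalg.norm(mean)
    return int(np.argmax(surf.sphere.vertices @ mean))


def _weighted_arc_mm(surf_sphere: np.ndarray, r_eff: float, indices: np.ndarray,
                     weights: np.ndarray, target_unit: np.ndarray) -> float:
    """Amplitude-weighted mean great-arc distance (converted to mm)."""
    dots = np.clip(surf_sphere[indices] @ target_unit, -1.0, 1.0)
    d = np.arccos(dots) * r_eff
    wsum = weights.sum()
    if wsum <= 0:
        return 0.0
    return float((weights * d).sum() / wsum)


def localization_error(values: np.ndarray, patch: SourcePatch, space: SourceSpace) -> float:
    """Extent-corrected localization error (mm) for one source patch.

    Raw error: the N strongest dipoles of the patch's hemisphere (N = patch
    size), amplitude-weighted mean arc distance to the true source location,
    converted to folded-cortex mm by the effective radius.  The source's
    self-extent (same formula on the patch with its own amplitudes) is
    subtracted and the result clamped at zero.
    """
    surf = space.surface(patch.hemisphere)
    mags = _hemi_magnitudes(values, space, patch.hemisphere)
    if not np.any(mags > 0):
        raise ValueError("estimate has no nonzero amplitude in the patch's hemisphere")
    r_eff = effective_radius(surf)
    center = _true_center_vertex(patch, space)
    target = surf.sphere.vertices[center]
    n = patch.size
    top = np.argsort(mags)[::-1][:n]
    raw = _weighted_arc_mm(surf.sphere.vertices, r_eff, top, mags[top], target)
    self_extent = _weighted_arc_mm(surf.sphere.vertices, r_eff, patch.vertices,
                                   np.abs(patch.amplitudes), target)
    return max(raw - self_extent, 0.0)


def amplitude_ratio(values: np.ndarray, patches: tuple[SourcePatch, SourcePatch],
                    space: SourceSpace) -> float:
    """Reconstructed strong/weak source-strength ratio across hemispheres.

    Mean of the N largest magnitudes in the hemisphere of the stronger true
    source over the same in the weaker's hemisphere; 2 for a perfect
    reconstruction of the standard 2:1 pair.
    """
    a, b = patches
    if a.hemisphere == b.hemisphere:
        raise ValueError("amplitude ratio is defined for sources in different hemispheres")
    strength = [np.abs(p.amplitudes).max() for p in patches]
    strong, weak = (a, b) if strength[0] >= strength[1] else (b, a)
    means = []
    for p in (strong, weak):
        mags = _hemi_magnitudes(values, space, p.hemisphere)
        top = np.sort(mags)[::-1][:p.size]
        means.append(top.mean())
    if means[1] == 0:
        raise ValueError("weaker hemisphere has an all-zero estimate")
    return float(means[0] / means[1])


def surface_bias(values: np.ndarray, patches, space: SourceSpace,
                 head_center: np.ndarray) -> float:
    """Relative outward displacement of the solution: (D_sol - D_src)/D_src.

    D is the amplitude-weighted mean Euclidean distance from the head centre
    over the 2N most active dipoles pooled across hemispheres (N per
    source); D_src uses the true patches with their own amplitudes.
    Positive values mean the solution sits closer to the scalp.
    """
    patches = list(np.atleast_1d(patches))
    rc = np.asarray(head_center, dtype=float)
    pos = space.positions_folded()
    mags = np.abs(np.asarray(values, dtype=float))
    n_sel = sum(p.size for p in patches)
    top = np.argsort(mags)[::-1][:n_sel]
    d_sol = float(np.sum(mags[top] * np.linalg.norm(pos[top] - rc, axis=1)) / mags[top].sum())
    src_idx = np.concatenate([space.global_index(p.hemisphere, p.vertices) for p in patches])
    src_amp = np.concatenate([np.abs(p.amplitudes) for p in patches])
    d_src = float(np.sum(src_amp * np.linalg.norm(pos[src_idx] - rc, axis=1)) / src_amp.sum())
    return (d_sol - d_src) / d_src


def _width_about_center(surf_sphere: np.ndarray, r_eff: float,
                        indices: np.ndarray, weights: np.ndarray) -> float:
    center = (weights[:, None] * surf_sphere[indices]).sum(axis=0)
    nrm = np.linalg.norm(center)
    if nrm == 0:
        return 0.0
    return _weighted_arc_mm(surf_sphere, r_eff, indices, weights, center / nrm)


def widths(values: np.ndarray, hemisphere: str, space: SourceSpace,
           n_strongest: int) -> tuple[float, float]:
    """(W_min, W_mid) in mm: spread about the solution's own weighted centre.

    W_min selects the ``n_strongest`` dipoles (hotspot size); W_mid selects
    every dipole above half the hemisphere's maximum amplitude (half-maximum
    spread).
    """
    surf = space.surface(hemisphere)
    mags = _hemi_magnitudes(values, space, hemisphere)
    if not np.any(mags > 0):
        raise ValueError("estimate has no nonzero amplitude in this hemisphere")
    r_eff = effective_radius(surf)
    sphere = surf.sphere.vertices
    top = np.argsort(mags)[::-1][:n_strongest]
    w_min = _width_about_center(sphere, r_eff, top, mags[top])
    half = np.flatnonzero(mags > 0.5 * mags.max())
    w_mid = _width_about_center(sphere, r_eff, half, mags[half])
    return w_min, w_mid


def source_width(patch: SourcePatch, space: SourceSpace) -> float:
    """W_min of the true patch itself (its amplitude-weighted self-spread)."""
    surf = space.surface(patch.hemisphere)
    return _width_about_center(surf.sphere.vertices, effective_radius(surf),
                               patch.vertices, np.abs(patch.amplitudes))


def coherence(values: np.ndarray, patch: SourcePatch, space: SourceSpace) -> float:
    """K_coh = W_min(source) / W_min(solution), capped at 1.

    1 means the solution's hotspot is as tight as the simulated source;
    smaller values mean a scattered, incoherent solution.  Undefined for
    single-dipole sources (zero self-width).
    """
    if patch.size <= 1:
        raise ValueError("coherence is not defined for single-dipole sources")
    w_src = source_width(patch, space)
    w_sol, _ = widths(values, patch.hemisphere, space, patch.size)
    if w_sol <= 0:
        return 1.0
    return min(w_src / w_sol, 1.0)


def congruency(w_mid_list, le_list) -> float:
    """Pearson correlation across configurations between W_mid and LE."""
    w = np.asarray(w_mid_list, dtype=float)
    e = np.asarray(le_list, dtype=float)
    if len(w) < 3 or len(w) != len(e):
        raise ValueError("need >= 3 paired configurations")
    if np.std(w) == 0 or np.std(e) == 0:
        raise ValueError("congruency undefined: zero variance in widths or errors")
    return float(np.corrcoef(w, e)[0, 1])


def auc(values: np.ndarray, patches, space: SourceSpace) -> float:
    """Rank-based overlap of the estimate with the true patches.

    Pools all source vertices (n_s); for each patch the same number of most
    active non-source vertices are drawn from its own hemisphere (n_ns =
    n_s); all 2 n_s magnitudes are ranked ascending with average ties, and
    AUC = (sum of source ranks - n_s(n_s+1)/2) / (n_s * n_ns) - exactly the
    pairwise probability that a source vertex out-ranks a selected
    non-source vertex.
    """
    patches = list(np.atleast_1d(patches))
    mags = np.abs(np.asarray(values, dtype=float))
    src_global = np.concatenate([space.global_index(p.hemisphere, p.vertices)
                                 for p in patches])
    src_set = set(src_global.tolist())
    ns_global = []
    for p in patches:
        sl = space.hemisphere_slice(p.hemisphere)
        hemi_idx = np.arange(sl.start, sl.stop)
        candidates = np.array([i for i in hemi_idx if i not in src_set])
        if len(candidates) < p.size:
            raise ValueError("not enough non-source vertices in the hemisphere")
        order = np.argsort(mags[candidates])[::-1][:p.size]
        ns_global.append(candidates[order])
    ns_global = np.concatenate(ns_global)
    pooled = np.concatenate([mags[src_global], mags[ns_global]])
    ranks = rankdata(pooled, method="average")
    n_s, n_ns = len(src_global), len(ns_global)
    return float((ranks[:n_s].sum() - n_s * (n_s + 1) / 2.0) / (n_s * n_ns))


# ----------------------------------------------------------------------------
# per-configuration driver


def evaluate_configuration(values: np.ndarray, patches, space: SourceSpace,
                           head_center: np.ndarray) -> dict:
    """All per-configuration measures for one estimate, L/R averaged.

    AR/LE/widths/coherence are skipped (NaN) for same-hemisphere pairs,
    where no per-source dipole assignment exists; coherence is NaN for
    single-dipole patches.
    """
    patches = list(np.atleast_1d(patches))
    hemis = {p.hemisphere for p in patches}
    cross = len(patches) == 2 and len(hemis) == 2
    single = len(patches) == 1
    row: dict[str, float] = {}
    if cross or single:
        les = [localization_error(values, p, space) for p in patches]
        row["LE"] = float(np.mean(les))
        w = [widths(values, p.hemisphere, space, p.size) for p in patches]
        row["W_min"] = float(np.mean([x[0] for x in w]))
        row["W_mid"] = float(np.mean([x[1] for x in w]))
        if all(p.size > 1 for p in patches):
            row["K_coh"] = float(np.mean([coherence(values, p, space) for p in patches]))
        else:
            row["K_coh"] = np.nan
        row["AR"] = amplitude_ratio(values, tuple(patches), space) if cross else np.nan
    else:
        row.update({"LE": np.nan, "W_min": np.nan, "W_mid": np.nan,
                    "K_coh": np.nan, "AR": np.nan})
    row["SB"] = surface_bias(values, patches, space, head_center)
    row["AUC"] = auc(values, patches, space) if all(p.size > 1 for p in patches) else np.nan
    return row


@dataclass
class MetricsReport:
    """Per-configuration measures (rows) and their aggregates per algorithm."""

    table: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        """Mean measures per algorithm, plus congruency across configurations."""
        rows = []
        for alg, grp in self.table.groupby("algorithm", sort=False):
            agg = grp[["LE", "AR", "SB", "W_min", "W_mid", "K_coh", "AUC"]].mean(skipna=True)
            ok = grp[["W_mid", "LE"]].dropna()
            agg["K_cong"] = (congruency(ok["W_mid"], ok["LE"])
                             if len(ok) >= 3 and ok["W_mid"].std() > 0 and ok["LE"].std() > 0
                             else np.nan)
            agg["algorithm"] = alg
            rows.append(agg)
        return pd.DataFrame(rows).set_index("algorithm")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json_summary(self, path) -> None:
        self.aggregate().to_json(path, orient="index", indent=1)
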