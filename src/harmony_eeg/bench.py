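"""Re-enactment of the two-source simulation study at configurable scale.

The standing test bed is fully synthetic: a folded two-hemisphere
pseudo-cortex inside the analytic three-shell head, a 128-channel
Fibonacci electrode net on the scalp shell, hexagonal 37-dipole (or
single-dipole) source patches driven outward at ~10 uV scalp amplitude
with a 2:1 left/right strength ratio, and spatially correlated sensor
noise.  Per algorithm, the regularization parameter is selected by OCV,
solutions are averaged over noise draws, and the quality measures of
:mod:`harmony_eeg.metrics` are tabulated per configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import metrics as qm
from .forward import (GainMatrix, SensorArray, fibonacci_sensors, layered_sphere_gain,
                      spatial_noise_covariance, synth_noise)
from .geometry import (SourcePatch, SourceSpace, head_center, icosphere,
                       k_ring_patch, make_two_hemisphere_space)
from .inverse import InverseOperator, apply, make_inverse_family, normalize
from .regularization import select_lambda

__all__ = [
    "SimulationConfig",
    "BenchmarkResult",
    "BenchContext",
    "make_context",
    "place_patch_grid",
    "make_patch",
    "simulate_measurement",
    "run_benchmark",
    "significance_vs_noise",
    "le_map",
]

_NORMALIZED = {"dspm": "dspm", "sloreta": "sloreta", "nharmony": "dspm", "nsplines": "dspm"}
_FAMILY_OF = {"dspm": "mne", "sloreta": "mne", "nharmony": "harmony", "nsplines": "splines"}


@dataclass
class SimulationConfig:
    """Study conditions; defaults are the reference simulation design."""

    mesh_level: int = 4
    patch_kind: str = "ring3"            # 'single' or 'ring3' (37 dipoles)
    amplitude_ratio: float = 2.0
    n_locations: int = 66                # patch locations per hemisphere
    pairing: str = "cross-hemisphere"    # or 'same-hemisphere'
    target_scalp_uv: float = 10.0
    noise_rms_uv: float = 1.0
    noise_length_scale_mm: float = 30.0
    n_noise: int = 100
    n_configurations: int | None = None  # None: one pair per location
    algorithms: tuple = ("harmony", "mne")
    orientation_mode: str = "constrained"
    l_max: int = 10
    gamma: float = 0.75
    h: float = 0.8
    depth_exponent: float = 1.0
    ibf_sigma: float = 10.0
    ibf_k: int = 512
    fold_amplitude: float = 4.0
    n_sensors: int = 128
    series_truncation: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_ratio <= 0:
            raise ValueError("amplitude_ratio must be > 0")
        for name in ("n_locations", "n_noise", "n_sensors", "mesh_level"):
            if getattr(self, name) < 0 or (name != "mesh_level" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.patch_kind not in ("single", "ring3"):
            raise ValueError("patch_kind must be 'single' or 'ring3'")
        if self.pairing not in ("cross-hemisphere", "same-hemisphere"):
            raise ValueError("pairing must be 'cross-hemisphere' or 'same-hemisphere'")


@dataclass
class BenchContext:
    """Shared fixture for one benchmark run: meshes, sensors, gain, noise."""

    space: SourceSpace
    sensors: SensorArray
    gain: GainMatrix
    noise_cov: np.ndarray
    head_center: np.ndarray
    config: SimulationConfig


@dataclass
class BenchmarkResult:
    table: pd.DataFrame
    aggregate: pd.DataFrame
    lambdas: dict
    config: SimulationConfig

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def make_context(config: SimulationConfig) -> BenchContext:
    space = make_two_hemisphere_space(config.mesh_level,
                                      fold_amplitude=config.fold_amplitude,
                                      seed=config.seed)
    sensors = fibonacci_sensors(config.n_sensors)
    gain = layered_sphere_gain(sensors, space,
                               series_truncation=config.series_truncation,
                               orientation_mode=config.orientation_mode)
    cov = spatial_noise_covariance(sensors, rms=config.noise_rms_uv * 1e-6,
                                   length_scale=config.noise_length_scale_mm).matrix
    return BenchContext(space, sensors, gain, cov, head_center(sensors.positions), config)


def place_patch_grid(surface, n_locations: int, seed: int = 0) -> np.ndarray:
    """Uniformly spread patch centre vertices on one hemisphere.

    Candidates are low-level icosphere nodes snapped to the nearest mesh
    vertices; a greedy farthest-point pass (seeded start) subsamples them to
    ``n_locations`` maximizing the minimum pairwise arc.
    """
    m = surface.sphere.n_vertices
    if n_locations > m:
        raise ValueError("n_locations exceeds vertex count")
    if n_locations == m:
        return np.arange(m)
    level = 0
    while 10 * 4**level + 2 < n_locations:
        level += 1
    level = min(level + 1, 6)  # oversample the candidate grid
    from scipy.spatial import cKDTree

    nodes = icosphere(level).vertices
    tree = cKDTree(surface.sphere.vertices)
    _, snapped = tree.query(nodes)
    candidates = np.unique(snapped)
    if len(candidates) < n_locations:
        candidates = np.arange(m)
    pos = surface.sphere.vertices[candidates]
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(len(candidates)))]
    min_dot = pos @ pos[chosen[0]]
    for _ in range(n_locations - 1):
        nxt = int(np.argmin(min_dot))  # farthest (smallest cosine) candidate
        chosen.append(nxt)
        min_dot = np.maximum(min_dot, pos @ pos[nxt])
    return np.sort(candidates[np.array(chosen)])


def make_patch(space: SourceSpace, hemisphere: str, center: int,
               kind: str, amplitude: float) -> SourcePatch:
    """Outward-oriented uniform patch: single dipole or 3-ring (37 dipoles)."""
    surf = space.surface(hemisphere)
    k = 0 if kind == "single" else 3
    patch = k_ring_patch(surf, center, k)
    patch.amplitudes = np.full(patch.size, float(amplitude))
    return patch


def simulate_measurement(gain: GainMatrix, patches, space: SourceSpace,
                         target_scalp_amplitude: float = 10e-6):
    """Scalp potentials of outward unit-moment patches, scaled to target.

    Within each patch all dipoles carry the same outward moment; the pair is
    scaled jointly so the maximum absolute scalp potential equals
    ``target_scalp_amplitude`` (V).  Returns (sensor vector, true source
    vector).  Patches must not overlap.
    """
    patches = list(np.atleast_1d(patches))
    s_true = np.zeros(gain.source_count)
    seen: set[int] = set()
    for p in patches:
        gidx = np.asarray(space.global_index(p.hemisphere, p.vertices))
        if seen.intersection(gidx.tolist()):
            raise ValueError("source patches overlap")
        seen.update(gidx.tolist())
        s_true[gidx] = p.amplitudes
    if gain.orientation_mode != "constrained":
        raise ValueError("simulation drives normal-constrained sources")
    v = gain.matrix @ s_true
    peak = np.abs(v).max()
    if target_scalp_amplitude == 0 or peak == 0:
        scale = 0.0
    else:
        scale = target_scalp_amplitude / peak
    for p in patches:
        p.amplitudes = p.amplitudes * scale
    return v * scale, s_true * scale


def _configurations(ctx: BenchContext, rng: np.random.Generator):
    """Seeded list of (left patch centre, right patch centre) or same-hemi pairs."""
    cfg = ctx.config
    centers = {s.hemisphere: place_patch_grid(s, cfg.n_locations, cfg.seed)
               for s in ctx.space.surfaces}
    pairs = []
    if cfg.pairing == "cross-hemisphere":
        li = rng.permutation(len(centers["left"]))
        ri = rng.permutation(len(centers["right"]))
        for a, b in zip(li, ri):
            pairs.append((("left", int(centers["left"][a])),
                          ("right", int(centers["right"][b]))))
    else:
        ring = 0 if cfg.patch_kind == "single" else 3
        for hemi in ("left", "right"):
            surf = ctx.space.surface(hemi)
            c = centers[hemi]
            members = {int(v): set(k_ring_patch(surf, int(v), ring).vertices.tolist())
                       for v in c}
            idx = rng.permutation(len(c))
            for a, b in zip(idx, np.roll(idx, 1)):
                if a == b or members[int(c[a])] & members[int(c[b])]:
                    continue  # coincident or overlapping patches are omitted
                pairs.append(((hemi, int(c[a])), (hemi, int(c[b]))))
    if cfg.n_configurations is not None:
        pairs = pairs[:cfg.n_configurations]
    return pairs


def _build_operators(ctx: BenchContext, v_for_ocv: np.ndarray):
    """Per-algorithm OCV-selected inverse operators (normalized when asked)."""
    cfg = ctx.config
    ops: dict[str, InverseOperator] = {}
    lambdas: dict[str, float] = {}
    families = {}
    for alg in cfg.algorithms:
        fam_name = _FAMILY_OF.get(alg, alg)
        if fam_name not in families:
            families[fam_name] = make_inverse_family(
                fam_name, ctx.gain, ctx.noise_cov, ctx.space,
                l_max=cfg.l_max, gamma=cfg.gamma, h=cfg.h,
                depth_exponent=cfg.depth_exponent,
                ibf_sigma=cfg.ibf_sigma, ibf_k=cfg.ibf_k)
        fam = families[fam_name]
        if fam_name not in lambdas:
            lambdas[fam_name] = select_lambda(v_for_ocv, fam).lam
        op = fam.operator(lambdas[fam_name])
        if alg in _NORMALIZED:
            op = normalize(op, _NORMALIZED[alg], G=ctx.gain, C=ctx.noise_cov)
        op.algorithm = alg
        ops[alg] = op
        lambdas[alg] = lambdas[fam_name]
    return ops, {a: lambdas[a] for a in cfg.algorithms}


def _patch_pair(ctx: BenchContext, pair):
    cfg = ctx.config
    (h1, c1), (h2, c2) = pair
    strong = make_patch(ctx.space, h1, c1, cfg.patch_kind, 1.0)
    weak = make_patch(ctx.space, h2, c2, cfg.patch_kind, 1.0 / cfg.amplitude_ratio)
    return [strong, weak]


def run_benchmark(config: SimulationConfig, ctx: BenchContext | None = None) -> BenchmarkResult:
    """Full seeded benchmark: configurations x noise draws x algorithms.

    For every configuration the clean scalp pattern is perturbed by
    ``n_noise`` seeded noise draws and the per-draw solutions are averaged
    (by linearity of W this is the solution of the draw-averaged data);
    measures are computed on the averaged solution and congruency across
    configurations at the end.
    """
    ctx = ctx or make_context(config)
    master = np.random.SeedSequence(config.seed)
    pair_rng = np.random.default_rng(master.spawn(1)[0])
    pairs = _configurations(ctx, pair_rng)
    if not pairs:
        raise ValueError("no source configurations to simulate")

    # operator construction and OCV on the first configuration's noisy data
    first_patches = _patch_pair(ctx, pairs[0])
    v0, _ = simulate_measurement(ctx.gain, first_patches, ctx.space,
                                 config.target_scalp_uv * 1e-6)
    noise_seed = int(master.spawn(2)[1].generate_state(1)[0] % (2**31))
    ocv_noise = synth_noise_from(ctx, config.n_noise, noise_seed)
    # OCV sees the noisy draws themselves (pooled), as in a real recording
    ops, lambdas = _build_operators(ctx, (v0[None, :] + ocv_noise).T)

    rows = []
    child_seeds = master.spawn(3 + len(pairs))[3:]
    for k, pair in enumerate(pairs):
        patches = _patch_pair(ctx, pair)
        v0, _ = simulate_measurement(ctx.gain, patches, ctx.space,
                                     config.target_scalp_uv * 1e-6)
        seed_k = int(child_seeds[k].generate_state(1)[0] % (2**31))
        noise = synth_noise_from(ctx, config.n_noise, seed_k)
        v_bar = v0 + noise.mean(axis=0)
        for alg, op in ops.items():
            est = apply(op, v_bar)
            row = qm.evaluate_configuration(est.values, patches, ctx.space,
                                            ctx.head_center)
            row.update({"algorithm": alg, "configuration": k,
                        "left": pair[0][1], "right": pair[1][1],
                        "pairing": config.pairing})
            rows.append(row)
    table = pd.DataFrame(rows)
    report = qm.MetricsReport(table)
    return BenchmarkResult(table, report.aggregate(), lambdas, config)


def synth_noise_from(ctx: BenchContext, n: int, seed: int) -> np.ndarray:
    return synth_noise(_CovShim(ctx.noise_cov), n, seed)


class _CovShim:
    def __init__(self, matrix):
        self.matrix = matrix


def significance_vs_noise(op: InverseOperator, v_clean: np.ndarray,
                          noise: np.ndarray, patch: SourcePatch,
                          space: SourceSpace, quantile: float = 0.95):
    """Is the reconstruction better than chance at this source location?

    Per noise draw, the localization error of the signal+noise solution is
    compared with that of the noise-only solution; the location passes when
    signal+noise wins in at least ``quantile`` of the draws.
    """
    if len(noise) < 20:
        raise ValueError("need >= 20 noise draws for the significance test")
    wins = 0
    for nk in noise:
        le_signal = qm.localization_error(apply(op, v_clean + nk).values, patch, space)
        le_noise = qm.localization_error(apply(op, nk).values, patch, space)
        wins += le_signal < le_noise
    rate = wins / len(noise)
    return rate >= quantile, rate


def le_map(config: SimulationConfig, grid_level: int = 4,
           n_locations: int | None = None, hemisphere: str = "left",
           ctx: BenchContext | None = None, algorithm: str | None = None) -> pd.DataFrame:
    """Single-source localization-error map with per-location significance.

    The source patch is placed at the nodes of a uniform icosphere grid
    (level 4: 2,562 nodes per hemisphere) snapped to the mesh;
    ``n_locations`` subsamples the grid for desk-scale runs.  Returns one
    row per tested location: vertex, LE (mm), significance, win rate.
    """
    ctx = ctx or make_context(config)
    surf = ctx.space.surface(hemisphere)
    from scipy.spatial import cKDTree

    nodes = icosphere(min(grid_level, config.mesh_level)).vertices
    tree = cKDTree(surf.sphere.vertices)
    _, centers = tree.query(nodes)
    centers = np.unique(centers)
    if n_locations is not None and n_locations < len(centers):
        rng = np.random.default_rng(config.seed)
        centers = np.sort(rng.choice(centers, n_locations, replace=False))

    alg = algorithm or config.algorithms[0]
    probe = make_patch(ctx.space, hemisphere, int(centers[0]), config.patch_kind, 1.0)
    v_probe, _ = simulate_measurement(ctx.gain, probe, ctx.space,
                                      config.target_scalp_uv * 1e-6)
    master = np.random.SeedSequence(config.seed)
    noise_seed = int(master.generate_state(1)[0] % (2**31))
    noise = synth_noise_from(ctx, config.n_noise, noise_seed)
    cfg_ops = SimulationConfig(**{**asdict(config), "algorithms": (alg,)})
    ctx_ops = BenchContext(ctx.space, ctx.sensors, ctx.gain, ctx.noise_cov,
                           ctx.head_center, cfg_ops)
    ops, _ = _build_operators(ctx_ops, v_probe + noise.mean(axis=0))
    op = ops[alg]

    rows = []
    for c in centers:
        patch = make_patch(ctx.space, hemisphere, int(c), config.patch_kind, 1.0)
        v0, _ = simulate_measurement(ctx.gain, patch, ctx.space,
                                     config.target_scalp_uv * 1e-6)
        est = apply(op, v0 + noise.mean(axis=0))
        le = qm.localization_error(est.values, patch, ctx.space)
        sig, rate = significance_vs_noise(op, v0, noise, patch, ctx.space)
        rows.append({"vertex": int(c), "LE": le, "significant": bool(sig), "win_rate": rate})
    return pd.DataFrame(rows)
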