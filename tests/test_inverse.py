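"""Inverse operators: algebraic identities, priors, normalization, thresholds."""

import numpy as np
import pytest
from scipy.stats import chi2, spearmanr

from harmony_eeg.basis import BasisSet, harmonics_T, identity_T
from harmony_eeg.forward import NoiseCovariance, synth_noise
from harmony_eeg.inverse import (InverseOperator, SourcePrior, apply, basis_inverse,
                                 depth_weights, f_threshold, harmony_prior, ibf_basis,
                                 linear_inverse, loreta_prior, make_inverse_family,
                                 normalize, solution_noise_sd)


def test_minimum_norm_limit_is_pseudoinverse(rng):
    """R = I, C = I, lambda -> 0+: W converges to the Moore-Penrose inverse."""
    g = rng.normal(size=(16, 200))
    lam = 1e-12 * np.trace(g @ g.T) / 16
    w = linear_inverse(g, np.eye(16), lam=lam).W
    assert np.abs(w - np.linalg.pinv(g)).max() < 1e-8


def test_shrinkage_with_large_lambda(rng):
    g = rng.normal(size=(12, 50))
    norms = [np.linalg.norm(linear_inverse(g, np.eye(12), lam=lam).W)
             for lam in (1e0, 1e2, 1e4, 1e6)]
    assert all(b < a for a, b in zip(norms, norms[1:]))


def test_row_space_recovery(rng):
    """Signals in the row space of G are recovered as lambda -> 0."""
    g = rng.normal(size=(10, 40))
    s = g.T @ rng.normal(size=10)  # row-space vector
    lam = 1e-12 * np.trace(g @ g.T) / 10
    w = linear_inverse(g, np.eye(10), lam=lam).W
    s_hat = w @ (g @ s)
    assert np.linalg.norm(s_hat - s) / np.linalg.norm(s) < 1e-6


def test_basis_identity_matches_linear_inverse(space2, rng):
    g = rng.normal(size=(14, space2.n_sources))
    c = np.eye(14)
    w_lin = linear_inverse(g, c, lam=0.5).W
    w_bas = basis_inverse(g, identity_T(space2), None, c, lam=0.5).W
    assert np.abs(w_lin - w_bas).max() < 1e-12


def test_complete_orthonormal_basis_reduces_to_mne(rng):
    """Any complete orthonormal T with identity prior gives the MNE solution."""
    g = rng.normal(size=(16, 200))
    q, _ = np.linalg.qr(rng.normal(size=(200, 200)))
    t = BasisSet(q.T, "harmonics", np.zeros(200, dtype=int))
    lam = 1e-12 * np.trace(g @ g.T) / 16
    w_mne = linear_inverse(g, np.eye(16), lam=lam).W
    w_bas = basis_inverse(g, t, None, np.eye(16), lam=lam).W
    assert np.abs(w_bas - w_mne).max() < 1e-8


def test_basis_path_equals_explicit_transformed_prior(rng):
    """Reduced-basis solve == dipole-space solve with prior T^T R_b T."""
    g = rng.normal(size=(10, 40))
    c = np.eye(10) + 0.1 * np.ones((10, 10))
    t = rng.normal(size=(12, 40))
    weights = rng.uniform(0.5, 2.0, size=12)
    b = BasisSet(t, "harmonics", np.zeros(12, dtype=int))
    lam = 0.3
    w_path6 = basis_inverse(g, b, SourcePrior("w", weights=weights), c, lam).W
    wn = weights / weights.mean()  # prior normalization convention
    r_dipole = t.T @ np.diag(wn) @ t
    w_path7 = r_dipole @ g.T @ np.linalg.inv(g @ r_dipole @ g.T + lam * c)
    assert np.abs(w_path6 - w_path7).max() < 1e-10


def test_harmony_prior_weights(space2):
    b = harmonics_T(space2, 5)
    p0 = harmony_prior(b, gamma=0.0)
    assert np.allclose(p0.weights, 1.0)
    p1 = harmony_prior(b, gamma=1.0)
    raw = (1.0 + np.asarray(b.labels, float)) ** -2.0
    assert np.allclose(p1.weights, raw / raw.mean())
    # non-increasing in l before normalization: check ratio at l=3 vs l=0
    l = np.asarray(b.labels)
    assert p1.weights[l == 3][0] / p1.weights[l == 0][0] == pytest.approx(1 / 16)
    assert np.all(np.diff(p1.weights[np.argsort(l, kind="stable")]) <= 1e-15)


def test_depth_weights_scaling_law(rng):
    g = rng.normal(size=(8, 20))
    w = depth_weights(g)
    g2 = g.copy()
    g2[:, 3] *= 0.5
    w2 = depth_weights(g2)
    assert w2[3] == pytest.approx(4.0 * w[3])
    uniform = depth_weights(np.tile(rng.normal(size=(8, 1)), (1, 5)))
    assert np.allclose(uniform, uniform[0])
    g3 = g.copy()
    g3[:, 7] = 0.0
    with pytest.raises(ValueError, match="7"):
        depth_weights(g3)


def test_depth_weights_track_source_depth():
    """Depth weights rise with depth when orientation/coverage confounds
    are controlled: radial dipoles, full-coverage sensor net."""
    from harmony_eeg.forward import fibonacci_sensors, layered_sphere_gain
    from harmony_eeg.geometry import SourceSpace, TriMesh, icosphere, CorticalSurface

    rng = np.random.default_rng(0)
    sph = icosphere(2)
    radii = rng.uniform(30.0, 75.0, size=sph.n_vertices)
    folded = sph.vertices * radii[:, None]
    surf = CorticalSurface("left", TriMesh(folded, sph.faces), sph, sph.vertices.copy())
    sens = fibonacci_sensors(64, upper_fraction=1.0)
    g = layered_sphere_gain(sens, SourceSpace([surf]), series_truncation=60)
    w = depth_weights(g)
    rho, _ = spearmanr(w, -radii)
    assert rho > 0.9


def test_loreta_laplacian_annihilates_constants(space2):
    from harmony_eeg.inverse import _mesh_graph_laplacian

    lap = _mesh_graph_laplacian(space2)
    ones = np.ones(space2.n_sources)
    assert np.abs(lap @ ones).max() < 1e-12


def test_loreta_prior_prefers_smooth_fields(space2, rng):
    """Prior quadratic form x^T R^-1 x penalizes rough fields more."""
    prior = loreta_prior(space2)
    lap = prior.params["laplacian"]
    rough = rng.choice([-1.0, 1.0], size=space2.n_sources)
    adj = {}
    # one smoothing pass: average over neighbours
    smooth = rough.copy()
    for surf, off in zip(space2.surfaces, space2.offsets):
        for v, nbrs in enumerate(surf.sphere.vertex_adjacency()):
            smooth[off + v] = rough[off + np.asarray(nbrs)].mean()

    def energy(x):
        y = lap @ x
        return float(y @ y)

    assert energy(smooth) < energy(rough)


def test_laplace_beltrami_eigenfunction_on_sphere():
    """Mass-normalized Laplacian reproduces l(l+1)/r^2 on a degree-1 harmonic."""
    from harmony_eeg.geometry import make_pseudo_cortex, SourceSpace
    from harmony_eeg.inverse import _mesh_graph_laplacian, _vertex_areas

    r = 50.0
    surf = make_pseudo_cortex(4, fold_amplitude=0.0, radius=r, midline_offset=0.0)
    space = SourceSpace([surf])
    lap = _mesh_graph_laplacian(space)
    areas = _vertex_areas(space)
    z = surf.folded.vertices[:, 2] / r  # degree-1 spherical harmonic (up to scale)
    lz = np.asarray(lap @ z) / areas    # approximates -Laplace_Beltrami(z)
    mask = np.abs(z) > 0.3
    ratios = lz[mask] / z[mask]
    target = 1 * 2 / r**2               # l(l+1)/r^2, l = 1
    assert abs(ratios.mean() - target) / target < 0.05
    assert ratios.std() / ratios.mean() < 0.05


def test_ibf_basis_spectrum_and_leading_vector():
    from harmony_eeg.geometry import make_two_hemisphere_space

    space = make_two_hemisphere_space(2, fold_amplitude=0.0, seed=0)
    basis, eig = ibf_basis(space, sigma=10.0, k_per_hemi=40)
    assert basis.K == 80
    assert np.all(eig >= 0)
    per_hemi = eig[:40]
    assert np.all(np.diff(per_hemi) <= 1e-9)
    # leading eigenvector of a smooth kernel on a uniform sphere is close to
    # constant; the graph-shortest-path metric is mildly anisotropic on a
    # triangulated sphere, which bounds the achievable uniformity
    rows, cols = basis.blocks["left"]
    lead = basis.T[rows.start, cols]
    assert np.abs(lead).std() / np.abs(lead).mean() < 0.10
    with pytest.raises(ValueError):
        ibf_basis(space, sigma=10.0, k_per_hemi=10**5)


def test_ibf_sigma_to_zero_is_identity(space2):
    basis, eig = ibf_basis(space2, sigma=1e-6, k_per_hemi=162)
    rows, cols = basis.blocks["left"]
    t = np.abs(basis.T[rows, cols])
    # eigenvectors of the identity: coordinate vectors (up to order/sign)
    assert np.allclose(np.sort(t.max(axis=1)), 1.0)
    assert np.allclose(eig, 1.0)


def test_solution_noise_sd_closed_form_and_monte_carlo(rng):
    w = rng.normal(size=(30, 12))
    assert np.allclose(solution_noise_sd(w, np.eye(12)), np.linalg.norm(w, axis=1))
    assert np.allclose(solution_noise_sd(w, np.zeros((12, 12))), 0.0)
    a = rng.normal(size=(12, 12)) / 4
    c = a @ a.T + 0.1 * np.eye(12)
    sd = solution_noise_sd(w, c)
    draws = synth_noise(NoiseCovariance(c), 20_000, seed=9)
    mc = (w @ draws.T).std(axis=1)
    assert np.abs(mc / sd - 1.0).max() < 0.03


def test_dspm_z_score_property(ctx3):
    """Noise-normalized pure-noise solutions have unit empirical SD."""
    fam = make_inverse_family("mne", ctx3.gain, ctx3.noise_cov, ctx3.space)
    op = fam.operator(fam.default_lambda_scale())
    dspm = normalize(op, "dspm", C=ctx3.noise_cov)
    noise = synth_noise(NoiseCovariance(ctx3.noise_cov), 1000, seed=17)
    sd = (dspm.W @ noise.T).std(axis=1)
    assert np.all(np.abs(sd - 1.0) < 0.10)


def test_sloreta_zero_localization_for_point_source(ctx3, rng):
    fam = make_inverse_family("mne", ctx3.gain, ctx3.noise_cov, ctx3.space)
    op = fam.operator(1e-6 * fam.default_lambda_scale())
    slo = normalize(op, "sloreta", G=ctx3.gain, C=ctx3.noise_cov)
    r = np.linalg.norm(ctx3.space.positions_folded(), axis=1)
    superficial = np.flatnonzero(r > np.quantile(r, 0.7))
    for j in rng.choice(superficial, 25, replace=False):
        est = apply(slo, ctx3.gain.matrix[:, j])
        assert int(np.argmax(np.abs(est.values))) == j


def test_normalization_guards(ctx3):
    fam = make_inverse_family("mne", ctx3.gain, ctx3.noise_cov, ctx3.space)
    op = fam.operator(fam.default_lambda_scale())
    with pytest.raises(ValueError):
        normalize(op, "volume")
    once = normalize(op, "dspm", C=ctx3.noise_cov)
    with pytest.raises(ValueError):
        normalize(once, "dspm", C=ctx3.noise_cov)  # scaling contract: once only


def test_f_threshold_quantile_and_type_one_error(rng):
    sigma = np.ones(500)
    thr = chi2.ppf(1 - 0.05 / 128, df=1)
    vals = np.zeros(500)
    assert not f_threshold(vals, sigma, 0.05, 128).any()
    edge = np.sqrt(thr) * 1.001
    assert f_threshold(np.full(500, edge), sigma, 0.05, 128).all()
    assert not f_threshold(np.full(500, np.sqrt(thr) * 0.999), sigma, 0.05, 128).any()
    # family-wise type-I rate over pure noise draws
    flags = 0
    for _ in range(1000):
        z = rng.standard_normal(128)
        flags += f_threshold(z, np.ones(128), 0.05, 128).any()
    assert flags / 1000 <= 0.05 + 0.02


def test_apply_linearity_and_shape_checks(ctx3, rng):
    fam = make_inverse_family("harmony", ctx3.gain, ctx3.noise_cov, ctx3.space)
    op = fam.operator(fam.default_lambda_scale())
    v1, v2 = rng.normal(size=(2, 128))
    lhs = apply(op, 2.0 * v1 - 3.0 * v2).values
    rhs = 2.0 * apply(op, v1).values - 3.0 * apply(op, v2).values
    assert np.abs(lhs - rhs).max() < 1e-12 * np.abs(rhs).max()
    assert np.allclose(apply(op, np.zeros(128)).values, 0.0)
    with pytest.raises(ValueError):
        apply(op, np.zeros(64))


def test_average_reference_null(ctx3):
    """W maps the all-ones sensor vector to numerically zero sources."""
    for alg in ("harmony", "mne", "wmne"):
        fam = make_inverse_family(alg, ctx3.gain, ctx3.noise_cov, ctx3.space)
        op = fam.operator(fam.default_lambda_scale())
        out = op.W @ np.ones(128)
        scale = np.abs(op.W).max()
        assert np.abs(out).max() < 1e-8 * scale * 128


def test_harmony_gamma_suppresses_high_degrees(ctx3):
    """Larger gamma monotonically reduces power above degree 6."""
    basis = harmonics_T(ctx3.space, 10)
    v = ctx3.gain.matrix[:, 100] + ctx3.gain.matrix[:, 700]
    high = np.asarray(basis.labels) > 6
    powers = []
    for gamma in (0.0, 0.5, 1.0, 1.5):
        fam = make_inverse_family("harmony", ctx3.gain, ctx3.noise_cov, ctx3.space,
                                  gamma=gamma)
        est = apply(fam.operator(fam.default_lambda_scale()), v)
        coeffs = np.linalg.lstsq(basis.T.T, est.values, rcond=None)[0]
        powers.append(float((coeffs[high] ** 2).sum()))
    assert all(b < a for a, b in zip(powers, powers[1:]))


def test_free_orientation_estimate_shapes(ctx3, rng):
    from harmony_eeg.forward import layered_sphere_gain

    g_free = layered_sphere_gain(ctx3.sensors, ctx3.space, series_truncation=40,
                                 orientation_mode="free")
    w = linear_inverse(g_free, ctx3.noise_cov, lam=1.0)
    est = apply(w, rng.normal(size=128))
    assert est.values.shape == (ctx3.space.n_sources, 3)
    assert est.magnitude.shape == (ctx3.space.n_sources,)
    sd = solution_noise_sd(w, ctx3.noise_cov)
    assert sd.shape == (ctx3.space.n_sources,)
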