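"""Layered-sphere forward model, gain I/O and noise covariance."""

import numpy as np
import pytest

from harmony_eeg.forward import (GainMatrix, NoiseCovariance, estimate_noise_covariance,
                                 fibonacci_sensors, layered_sphere_gain, load_gain,
                                 save_gain, spatial_noise_covariance, synth_noise,
                                 _shell_transfer)
from harmony_eeg.geometry import CorticalSurface, SourceSpace, TriMesh, icosphere


def _single_dipole_space(position, direction=None):
    """Minimal source space whose dipole 0 sits exactly at ``position``."""
    sph = icosphere(0)
    folded = sph.vertices * (np.linalg.norm(position) * 0.5)
    folded[0] = position
    normals = sph.vertices.copy()
    if direction is not None:
        normals[0] = direction / np.linalg.norm(direction)
    surf = CorticalSurface("left", TriMesh(folded, sph.faces), sph, normals)
    return SourceSpace([surf])


RADII = (80.0, 85.0, 92.0)
SIGMAS = (1.0, 1.0 / 30.0, 1.0)


def test_shell_transfer_homogeneous_closed_form():
    """Equal conductivities reduce to the single-sphere result (2n+1)/n."""
    rho1, rho2 = RADII[0] / RADII[2], RADII[1] / RADII[2]
    ns = np.arange(1, 41, dtype=float)
    t = _shell_transfer(40, rho1, rho2, (1.0, 1.0, 1.0))
    assert np.allclose(t / rho1 ** (ns + 1), (2 * ns + 1) / ns, rtol=1e-12)


def _oracle_monopole_surface(r0, sens_u, n_max=200):
    """Independent layered-sphere monopole potential (raw-variable solve).

    Textbook expansion: region-1 source q/(4 pi s1 |r-r0|) with coefficients
    q b^n / (4 pi s1 R^(n+1)) on P_n; interface continuity of V and of
    sigma dV/dr, insulating scalp.  Unknowns are the unscaled A_k, B_k in
    units of the outer radius; n = 0 is dropped (it cancels in dipole pairs).
    """
    R = RADII[2]
    rho1, rho2 = RADII[0] / R, RADII[1] / R
    s1, s2, s3 = SIGMAS
    b = np.linalg.norm(r0) / R
    d_hat = np.asarray(r0) / np.linalg.norm(r0)
    cosg = np.clip(sens_u @ d_hat, -1.0, 1.0)
    from numpy.polynomial.legendre import legval

    V = np.zeros(len(sens_u))
    for n in range(1, n_max + 1):
        c = b**n / (4 * np.pi * s1 * R)
        # unknowns A1,A2,B2,A3,B3 ; rows: V and flux at rho1, rho2; flux at 1
        m = np.array([
            [rho1**n, -rho1**n, -rho1 ** -(n + 1), 0, 0],
            [s1 * n * rho1 ** (n - 1), -s2 * n * rho1 ** (n - 1),
             s2 * (n + 1) * rho1 ** -(n + 2), 0, 0],
            [0, rho2**n, rho2 ** -(n + 1), -(rho2**n), -(rho2 ** -(n + 1))],
            [0, s2 * n * rho2 ** (n - 1), -s2 * (n + 1) * rho2 ** -(n + 2),
             -s3 * n * rho2 ** (n - 1), s3 * (n + 1) * rho2 ** -(n + 2)],
            [0, 0, 0, n, -(n + 1)],
        ])
        rhs = np.array([
            -c * rho1 ** -(n + 1),
            c * s1 * (n + 1) * rho1 ** -(n + 2),
            0.0, 0.0, 0.0,
        ])
        a1, a2, b2, a3, b3 = np.linalg.solve(m, rhs)
        coeffs = np.zeros(n + 1)
        coeffs[n] = 1.0
        V += (a3 + b3) * legval(cosg, coeffs)
    return V


def test_dipole_gain_matches_finite_difference_of_monopoles(rng):
    """Two opposite monopoles a small step apart approximate the dipole."""
    r0 = np.array([22.0, -15.0, 38.0])
    m = rng.normal(size=3)
    m /= np.linalg.norm(m)
    sens = fibonacci_sensors(24)
    sens_u = sens.positions / np.linalg.norm(sens.positions, axis=1, keepdims=True)
    delta = 1e-3
    v_fd = (_oracle_monopole_surface(r0 + 0.5 * delta * m, sens_u)
            - _oracle_monopole_surface(r0 - 0.5 * delta * m, sens_u)) / delta
    v_fd -= v_fd.mean()  # oracle lacks the average reference
    space = _single_dipole_space(r0)
    G = layered_sphere_gain(sens, space, RADII, SIGMAS,
                            series_truncation=200, orientation_mode="free")
    v_pkg = G.matrix[:, 0:3] @ m
    assert np.abs(v_pkg - v_fd).max() < 1e-6 * np.abs(v_fd).max()


def test_axial_symmetry_radial_dipole():
    """Radial dipole on the z-axis: equal potential at equal polar angle."""
    r0 = np.array([0.0, 0.0, 50.0])
    space = _single_dipole_space(r0, direction=np.array([0.0, 0.0, 1.0]))
    theta = np.deg2rad(55.0)
    phis = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    ring = 92.0 * np.column_stack([np.sin(theta) * np.cos(phis),
                                   np.sin(theta) * np.sin(phis),
                                   np.full_like(phis, np.cos(theta))])
    sens = fibonacci_sensors(16)
    sens.positions[:12] = ring
    G = layered_sphere_gain(sens, space, RADII, SIGMAS, series_truncation=100)
    v = G.matrix[:12, 0]
    assert np.abs(v - v.mean()).max() < 1e-10 * np.abs(v.mean())


def test_monotone_decay_from_dipole_axis():
    """Superficial radial dipole: potential decays with angular distance."""
    r0 = np.array([0.0, 0.0, 65.0])
    space = _single_dipole_space(r0, direction=np.array([0.0, 0.0, 1.0]))
    thetas = np.linspace(0.0, np.pi, 40)
    arc = 92.0 * np.column_stack([np.sin(thetas), np.zeros_like(thetas), np.cos(thetas)])
    sens = fibonacci_sensors(40)
    sens.positions[:] = arc
    G = layered_sphere_gain(sens, space, RADII, SIGMAS, series_truncation=150)
    v = G.matrix[:, 0]
    assert np.all(np.diff(v) < 0)


def test_linearity_and_average_reference(ctx3):
    G = ctx3.gain.matrix
    assert np.abs(G.sum(axis=0)).max() < 1e-10 * np.abs(G).max()
    s = np.zeros(ctx3.gain.source_count)
    s[37] = 2.0
    assert np.allclose(G @ s, 2.0 * G[:, 37], atol=0.0)
    assert np.allclose(G @ np.zeros_like(s), 0.0)


def test_truncation_self_convergence(ctx3):
    """Interior dipoles: truncation 60 vs 200 agree to 1e-6 relative."""
    pos = ctx3.space.positions_folded()
    r = np.linalg.norm(pos, axis=1)
    deep = np.flatnonzero(r <= 0.85 * RADII[0])
    sens = fibonacci_sensors(32)
    sub = _subspace(ctx3.space, deep[:40])
    g60 = layered_sphere_gain(sens, sub, RADII, SIGMAS, series_truncation=60)
    g200 = layered_sphere_gain(sens, sub, RADII, SIGMAS, series_truncation=200)
    denom = np.abs(g200.matrix).max()
    assert np.abs(g60.matrix - g200.matrix).max() < 1e-6 * denom


def _subspace(space, global_idx):
    """Tiny one-hemisphere space holding selected dipoles of ``space``."""
    sph = icosphere(1)
    pos = space.positions_folded()[global_idx]
    nrm = space.normals()[global_idx]
    folded = sph.vertices * 10.0
    normals = sph.vertices.copy()
    folded[:len(global_idx)] = pos
    normals[:len(global_idx)] = nrm
    surf = CorticalSurface("left", TriMesh(folded, sph.faces), sph, normals)
    return SourceSpace([surf])


def test_gain_geometry_guards(ctx3):
    sens = fibonacci_sensors(16)
    space = _single_dipole_space(np.array([0.0, 0.0, 81.0]))
    with pytest.raises(ValueError, match="inner shell"):
        layered_sphere_gain(sens, space, RADII, SIGMAS)
    with pytest.raises(ValueError, match="conductivities"):
        layered_sphere_gain(sens, _single_dipole_space(np.array([0, 0, 40.0])),
                            RADII, (1.0, -1.0, 1.0))
    with pytest.raises(ValueError, match="truncation"):
        layered_sphere_gain(sens, _single_dipole_space(np.array([0, 0, 40.0])),
                            RADII, SIGMAS, series_truncation=10)


def test_gain_round_trip(tmp_path, ctx3):
    for suffix in (".txt", ".h5"):
        path = tmp_path / f"gain{suffix}"
        save_gain(ctx3.gain, path)
        back = load_gain(path)
        if suffix == ".h5":
            assert np.array_equal(back.matrix, ctx3.gain.matrix)  # bit-identical
        else:
            assert np.allclose(back.matrix, ctx3.gain.matrix, rtol=1e-12)
        assert back.orientation_mode == "constrained"


def test_load_gain_contract_errors(tmp_path, rng):
    path = tmp_path / "g.txt"
    np.savetxt(path, rng.normal(size=(8, 30)))
    with pytest.raises(ValueError):
        load_gain(path)  # no orientation metadata
    with pytest.raises(ValueError):
        # 3M columns declared constrained with explicit M: contract violation
        load_gain(path, orientation_mode="constrained", source_count=10)
    odd = tmp_path / "g2.txt"
    np.savetxt(odd, rng.normal(size=(8, 31)))
    with pytest.raises(ValueError):
        load_gain(odd, orientation_mode="free")  # column count not divisible by 3


def test_noise_covariance_estimation(rng):
    n = 24
    a = rng.normal(size=(n, n)) / np.sqrt(n)
    sigma = a @ a.T + 0.5 * np.eye(n)
    half = np.linalg.cholesky(sigma)
    epochs = rng.standard_normal((10_000, n)) @ half.T
    est = estimate_noise_covariance(epochs)
    err = np.linalg.norm(est.matrix - sigma) / np.linalg.norm(sigma)
    assert err < 0.05
    same = estimate_noise_covariance(np.tile(epochs[0], (5, 1)))
    assert np.allclose(same.matrix, 0.0)
    diag = estimate_noise_covariance(epochs, shrinkage=1.0)
    assert np.allclose(diag.matrix, np.diag(np.diag(diag.matrix)))
    with pytest.raises(ValueError):
        estimate_noise_covariance(epochs[:1])


def test_synth_noise_moments(sensors128):
    cov = spatial_noise_covariance(sensors128, rms=1e-6, length_scale=30.0)
    # per-sensor variance stays at the rms^2 scale (the average-reference
    # projection removes a small common-mode share)
    diag = np.diag(cov.matrix)
    assert np.all((diag > 0.8e-12) & (diag <= 1e-12 + 1e-24))
    ones = np.ones(cov.matrix.shape[0])
    gap = cov.matrix @ ones - (ones @ cov.matrix @ ones / len(ones)) * ones
    assert np.abs(gap).max() < 1e-24  # reference direction is an eigenvector
    draws = synth_noise(cov, 100_000, seed=3)
    sample = draws.T @ draws / len(draws)
    assert np.linalg.norm(sample - cov.matrix) / np.linalg.norm(cov.matrix) < 0.03
    again = synth_noise(cov, 100, seed=42)
    assert np.array_equal(again, synth_noise(cov, 100, seed=42))
    zero = synth_noise(NoiseCovariance(np.zeros((4, 4))), 10, seed=0)
    assert np.allclose(zero, 0.0)


def test_noise_rms_within_evoked_residual_budget(sensors128):
    """Default synthetic noise stays at or below 1 uV RMS per sensor."""
    cov = spatial_noise_covariance(sensors128)
    rms = np.sqrt(np.diag(cov.matrix))
    assert np.all(rms <= 1e-6 + 1e-18)
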