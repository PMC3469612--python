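"""Forward modelling: gain matrices and sensor-noise covariance.

The toolkit never computes a BEM/FEM forward; gain matrices are either
imported from file or generated by the analytic concentric three-shell
conductor model implemented here, which retains the skull's spatial
low-pass effect that motivates smooth source bases.  Potentials are
average-referenced, matching the EEG convention used throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import SourceSpace

__all__ = [
    "SensorArray",
    "GainMatrix",
    "NoiseCovariance",
    "fibonacci_sensors",
    "layered_sphere_gain",
    "save_gain",
    "load_gain",
    "estimate_noise_covariance",
    "spatial_noise_covariance",
    "synth_noise",
]


@dataclass
class SensorArray:
    """EEG sensor labels and 3-D positions (mm), average-referenced."""

    labels: list[str]
    positions: np.ndarray
    reference: str = "average"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != len(self.positions) or len(self.labels) < 2:
            raise ValueError("need >= 2 sensors with one label per position")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("sensor labels must be unique")

    @property
    def n_sensors(self) -> int:
        return len(self.labels)

    @classmethod
    def read(cls, path) -> "SensorArray":
        """Read a whitespace/CSV text file: label x y z (mm) per row."""
        labels, rows = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
        return cls(labels, np.array(rows))

    def write(self, path) -> None:
        lines = [f"{lab} {x:.6f} {y:.6f} {z:.6f}"
                 for lab, (x, y, z) in zip(self.labels, self.positions)]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class GainMatrix:
    """Sensors x sources forward operator (V per unit dipole moment).

    ``orientation_mode`` is ``"constrained"`` (one column per dipole, moment
    along the outward normal) or ``"free"`` (three columns per dipole, x/y/z).
    """

    matrix: np.ndarray
    orientation_mode: str
    source_count: int
    reference_applied: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        expected = self.source_count * (3 if self.orientation_mode == "free" else 1)
        if self.orientation_mode not in ("constrained", "free"):
            raise ValueError("orientation_mode must be 'constrained' or 'free'")
        if self.matrix.shape[1] != expected:
            raise ValueError(
                f"gain has {self.matrix.shape[1]} columns, expected {expected} "
                f"for {self.source_count} {self.orientation_mode} sources")

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    def apply_average_reference(self) -> "GainMatrix":
        m = self.matrix - self.matrix.mean(axis=0, keepdims=True)
        return GainMatrix(m, self.orientation_mode, self.source_count, True)


@dataclass
class NoiseCovariance:
    """Symmetric PSD sensors x sensors covariance (V^2) with provenance."""

    matrix: np.ndarray
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("covariance must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10 * max(1.0, np.abs(self.matrix).max())):
            raise ValueError("covariance must be symmetric")
        w = np.linalg.eigvalsh(self.matrix)
        if w.min() < -1e-12 * max(self.matrix.trace(), 1e-300):
            raise ValueError("covariance must be positive semi-definite")


def fibonacci_sensors(n: int = 128, radius: float = 92.0,
                      upper_fraction: float = 0.75) -> SensorArray:
    """Quasi-uniform electrode net on the outer-shell sphere (Fibonacci lattice).

    Covers the upper ``upper_fraction`` of the sphere (EEG caps leave the
    underside of the head bare).
    """
    k = np.arange(n)
    # z spans [1 - 2*f, 1]: top cap of relative height f
    z = 1.0 - (2.0 * upper_fraction) * (k + 0.5) / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * k
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pos = radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    labels = [f"E{i + 1}" for i in range(n)]
    return SensorArray(labels, pos)


# ----------------------------------------------------------------------------
# analytic layered-sphere forward


def _shell_transfer(n_max: int, rho1: float, rho2: float, sigmas) -> np.ndarray:
    """Per-degree surface transfer t_n for a concentric 3-shell conductor.

    For each degree n the interface/boundary conditions give a 5x5 linear
    system in the scaled expansion coefficients; ``t_n`` maps the source
    coefficient (normalized at the inner interface) to the outer-surface
    potential coefficient.  For equal conductivities t_n = (2n+1)/n, the
    homogeneous-sphere closed form.
    """
    s1, s2, s3 = sigmas
    ns = np.arange(1, n_max + 1, dtype=float)
    r12n = (rho1 / rho2) ** ns          # (rho1/rho2)^n
    r12n1 = (rho1 / rho2) ** (ns + 1)
    r2n = rho2 ** ns
    r2n1 = rho2 ** (ns + 1)
    zeros = np.zeros_like(ns)
    ones = np.ones_like(ns)
    # unknowns: A1, A2, B2, A3, B3 (scaled: see docstring of layered_sphere_gain)
    A = np.zeros((n_max, 5, 5))
    b = np.zeros((n_max, 5))
    # potential continuity at rho1:  A1 + 1 = A2*(rho1/rho2)^n + B2
    A[:, 0] = np.stack([ones, -r12n, -ones, zeros, zeros], axis=1)
    b[:, 0] = -1.0
    # radial current continuity at rho1
    A[:, 1] = np.stack([s1 * ns, -s2 * ns * r12n, s2 * (ns + 1), zeros, zeros], axis=1)
    b[:, 1] = s1 * (ns + 1)
    # potential continuity at rho2:  A2 + B2*(rho1/rho2)^(n+1) = A3*rho2^n + B3
    A[:, 2] = np.stack([zeros, ones, r12n1, -r2n, -ones], axis=1)
    # radial current continuity at rho2
    A[:, 3] = np.stack([zeros, s2 * ns, -s2 * (ns + 1) * r12n1,
                        -s3 * ns * r2n, s3 * (ns + 1)], axis=1)
    # insulating outer boundary at rho=1:  n*A3 - (n+1)*B3*rho2^(n+1) = 0
    A[:, 4] = np.stack([zeros, zeros, zeros, ns, -(ns + 1) * r2n1], axis=1)
    sol = np.linalg.solve(A, b[:, :, None])[:, :, 0]
    # outer-surface potential coefficient: V(1) = A3 + B3*rho2^(n+1)
    return sol[:, 3] + sol[:, 4] * r2n1


def layered_sphere_gain(sensors: SensorArray, space: SourceSpace,
                        radii=(80.0, 85.0, 92.0), conductivities=(1.0, 1.0 / 30.0, 1.0),
                        series_truncation: int = 100,
                        orientation_mode: str = "constrained") -> GainMatrix:
    """Average-referenced gain for dipoles inside a concentric 3-shell head.

    Shells (inner to outer): brain/CSF, skull, scalp, with radii in mm and
    relative conductivities; defaults (80, 85, 92) mm and (1, 1/30, 1).  The
    potential of each unit dipole is the truncated Legendre series of the
    layered-sphere solution; constrained mode projects the three Cartesian
    components onto the outward cortical normals.

    Sensors are projected radially onto the outer shell (an error if they sit
    more than 2% off it); dipoles must lie strictly inside the inner shell.
    """
    if len(radii) != 3 or not np.all(np.diff(radii) > 0):
        raise ValueError("radii must be 3 increasing values (mm)")
    if np.any(np.asarray(conductivities) <= 0):
        raise ValueError("conductivities must be positive")
    n_max = int(series_truncation)
    if n_max < 20:
        raise ValueError("series_truncation must be >= 20")
    if orientation_mode not in ("constrained", "free"):
        raise ValueError("orientation_mode must be 'constrained' or 'free'")

    R = float(radii[2])
    rho1, rho2 = radii[0] / R, radii[1] / R
    dip_pos = space.positions_folded()
    dip_r = np.linalg.norm(dip_pos, axis=1)
    if np.any(dip_r >= radii[0]):
        worst = int(np.argmax(dip_r))
        raise ValueError(
            f"dipole {worst} at radius {dip_r[worst]:.2f} mm is not strictly "
            f"inside the inner shell ({radii[0]:.2f} mm)")

    sens_r = np.linalg.norm(sensors.positions, axis=1)
    if np.any(np.abs(sens_r / R - 1.0) > 0.02):
        raise ValueError("sensor positions deviate more than 2% from the outer shell radius")
    sens_u = sensors.positions / sens_r[:, None]

    sigma1 = float(conductivities[0])
    t_n = _shell_transfer(n_max, rho1, rho2, conductivities)  # (n_max,)
    ns = np.arange(1, n_max + 1, dtype=float)

    M = space.n_sources
    n_sens = sensors.n_sensors
    normals = space.normals()
    out_cols = 3 * M if orientation_mode == "free" else M
    G = np.empty((n_sens, out_cols))

    rho_b = dip_r / R
    for j in range(M):
        d_hat = dip_pos[j] / dip_r[j] if dip_r[j] > 0 else np.array([0.0, 0.0, 1.0])
        cosa = np.clip(sens_u @ d_hat, -1.0, 1.0)
        # tangential unit vector from dipole axis toward each sensor
        sina = np.sqrt(np.clip(1.0 - cosa**2, 0.0, None))
        t_vec = sens_u - cosa[:, None] * d_hat[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            t_vec = np.where(sina[:, None] > 1e-12, t_vec / np.where(sina > 1e-12, sina, 1.0)[:, None], 0.0)
        # Legendre P_n(cosa) and P_n^1(cosa) = sin(a) * dP_n/dx, by recurrence
        # degree-weighted radial decay: (rho_b/rho1)^(n-1) / rho1^2
        ratio = rho_b[j] / rho1
        decay = t_n * np.power(ratio, ns - 1.0) / (rho1**2 * 4.0 * np.pi * sigma1 * R**2)
        p_prev = np.ones_like(cosa)        # P_0
        p_cur = cosa.copy()                # P_1
        dp_prev = np.zeros_like(cosa)      # P_0'
        dp_cur = np.ones_like(cosa)        # P_1'
        v_rad = decay[0] * 1.0 * p_cur     # n * P_n term, n = 1
        v_tan = decay[0] * sina * dp_cur   # P_n^1 term
        for n in range(2, n_max + 1):
            p_next = ((2 * n - 1) * cosa * p_cur - (n - 1) * p_prev) / n
            dp_next = dp_prev + (2 * n - 1) * p_cur
            p_prev, p_cur = p_cur, p_next
            dp_prev, dp_cur = dp_cur, dp_next
            v_rad += decay[n - 1] * n * p_cur
            v_tan += decay[n - 1] * sina * dp_cur
        # potentials for unit moments along x, y, z:
        #   V = (m . d_hat) * v_rad + (m . t_vec) * v_tan
        cols = d_hat[None, :] * v_rad[:, None] + t_vec * v_tan[:, None]
        if orientation_mode == "free":
            G[:, 3 * j:3 * j + 3] = cols
        else:
            G[:, j] = cols @ normals[j]

    G -= G.mean(axis=0, keepdims=True)
    return GainMatrix(G, orientation_mode, M, True)


# ----------------------------------------------------------------------------
# gain I/O


def save_gain(gain: GainMatrix, path) -> None:
    """Save as delimited text (.txt) or HDF5 (.h5) with a JSON sidecar."""
    path = Path(path)
    meta = {
        "orientation_mode": gain.orientation_mode,
        "source_count": gain.source_count,
        "reference_applied": gain.reference_applied,
        "units": "V per unit dipole moment",
    }
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("gain", data=gain.matrix)
            for k, v in meta.items():
                d.attrs[k] = v
    else:
        np.savetxt(path, gain.matrix)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_gain(path, orientation_mode: str | None = None,
              source_count: int | None = None) -> GainMatrix:
    """Load a gain matrix saved by :func:`save_gain` or a bare matrix file.

    For bare files ``orientation_mode`` (and ``source_count``, if constrained
    columns cannot be inferred) must be supplied; a free-orientation file whose
    column count is not divisible by 3 is a format error.  The average
    reference is applied on load if the metadata does not claim it already.
    """
    path = Path(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            d = f["gain"]
            matrix = d[()]
            meta = {**{k: d.attrs[k] for k in d.attrs}, **meta}
    else:
        matrix = np.loadtxt(path)
    mode = orientation_mode or meta.get("orientation_mode")
    if mode is None:
        raise ValueError("orientation_mode not recorded in metadata and not supplied")
    if mode == "free":
        if matrix.shape[1] % 3:
            raise ValueError("free-orientation gain column count must be divisible by 3")
        count = int(meta.get("source_count", matrix.shape[1] // 3))
    else:
        count = int(meta.get("source_count", source_count or matrix.shape[1]))
    if source_count is not None and count != source_count:
        raise ValueError(f"gain has {count} sources, expected {source_count}")
    gain = GainMatrix(matrix, mode, count, bool(meta.get("reference_applied", False)))
    if not gain.reference_applied:
        gain = gain.apply_average_reference()
    return gain


# ----------------------------------------------------------------------------
# noise


def estimate_noise_covariance(noise_epochs: np.ndarray, shrinkage: float = 0.0) -> NoiseCovariance:
    """Empirical covariance of noise epochs, shrunk toward its diagonal.

    Epochs are (n_epochs, n_sensors); the across-epoch mean is subtracted
    first (projecting out any common evoked component), then
    C = (1-shrinkage)*S + shrinkage*diag(S).  PSD by construction.
    """
    x = np.asarray(noise_epochs, dtype=float)
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("need >= 2 epochs of shape (n_epochs, n_sensors)")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    xc = x - x.mean(axis=0, keepdims=True)
    s = xc.T @ xc / (len(x) - 1)
    c = (1.0 - shrinkage) * s + shrinkage * np.diag(np.diag(s))
    return NoiseCovariance(c, {"n_epochs": len(x), "shrinkage": shrinkage})


def spatial_noise_covariance(sensors: SensorArray, rms: float = 1e-6,
                             length_scale: float = 30.0) -> NoiseCovariance:
    """Spatially correlated sensor-noise covariance: rms^2 * exp(-d^2/2l^2).

    ``rms`` is the per-sensor noise RMS in volts (default 1 uV, the residual
    level of an averaged evoked recording); ``length_scale`` in mm.  The
    squared-exponential kernel is PSD for any sensor layout.  The covariance
    is expressed in the average-reference convention: the common-mode
    direction is made an exact eigenvector (its variance set to the removed
    mean), so average-referenced operators null it cleanly and the matrix
    stays full rank.
    """
    d = np.linalg.norm(sensors.positions[:, None, :] - sensors.positions[None, :, :], axis=-1)
    c = rms**2 * np.exp(-(d**2) / (2.0 * length_scale**2))
    n = len(c)
    ones = np.ones(n)
    common = float(ones @ c @ ones) / n**2
    proj = np.eye(n) - np.outer(ones, ones) / n
    c = proj @ c @ proj + common * np.outer(ones, ones) / n
    return NoiseCovariance(c, {"model": "squared-exponential", "rms": rms,
                               "length_scale_mm": length_scale})


def synth_noise(covariance: NoiseCovariance, n_samples: int, seed: int) -> np.ndarray:
    """Zero-mean Gaussian draws (n_samples, n_sensors) with the given covariance."""
    rng = np.random.default_rng(seed)
    c = covariance.matrix
    w, v = np.linalg.eigh(c)
    w = np.clip(w, 0.0, None)
    half = v * np.sqrt(w)[None, :]
    z = rng.standard_normal((n_samples, c.shape[0]))
    return z @ half.T
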