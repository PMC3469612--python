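"""Source-space basis transforms: spherical harmonics and Abel-Poisson splines.

A basis set is a K x M matrix T whose rows are global smooth functions
evaluated at the M dipole vertices of the sphere-mapped cortices.  Seeking
the inverse solution in the span of T (K << M) is what makes the
reconstruction parsimonious: the skull low-passes cortical potentials, so
high spatial frequencies carry sensor noise rather than signal.  T is
block-diagonal over hemispheres - a basis function on the left cortex has
exactly zero coupling to right-hemisphere dipoles.
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

from .geometry import SourceSpace, icosphere

__all__ = [
    "BasisSet",
    "harmonics_T",
    "splines_T",
    "identity_T",
    "nyquist_cutoff",
    "abel_poisson_kernel",
    "encode_coefficients",
    "decode_coefficients",
]


@dataclass
class BasisSet:
    """K x M transform from a global basis to dipole amplitudes.

    ``labels`` holds per-row metadata: harmonic degree l (kind='harmonics'),
    centre vertex (kind='splines'/'ibf'), or row index (identity).
    ``blocks`` maps hemisphere name -> (row slice, column slice).
    """

    T: np.ndarray
    kind: str
    labels: np.ndarray
    blocks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if self.T.shape[0] > self.T.shape[1]:
            raise ValueError("basis must have K <= M")
        if len(self.labels) != self.T.shape[0]:
            raise ValueError("one label per basis row required")

    @property
    def K(self) -> int:
        return self.T.shape[0]

    @property
    def M(self) -> int:
        return self.T.shape[1]


def real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real orthonormal spherical harmonic without Condon-Shortley phase.

    ``theta`` is the colatitude from the +z pole, ``phi`` the azimuth.  The
    cosine branch is returned for m > 0, the sine branch for m < 0.
    """
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    # sqrt(2)*(-1)^m undoes the Condon-Shortley phase of scipy's convention
    factor = math.sqrt(2.0) * (-1.0) ** abs(m)
    return factor * (np.real(y) if m > 0 else np.imag(y))


def _angles(unit_positions: np.ndarray):
    x, y, z = unit_positions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.mod(np.arctan2(y, x), 2.0 * np.pi)
    return theta, phi


def harmonics_T(space: SourceSpace, l_max: int) -> BasisSet:
    """Real spherical-harmonic basis up to degree ``l_max`` per hemisphere.

    Rows enumerate (l, m) with l = 0..l_max, m = -l..l ((l_max+1)^2 per
    hemisphere), evaluated at each dipole's spherical angles on the inflated
    cortex; the full T is block-diagonal over hemispheres.
    """
    if l_max < 0:
        raise ValueError("l_max must be >= 0")
    k_hemi = (l_max + 1) ** 2
    n_hemi = len(space.surfaces)
    T = np.zeros((k_hemi * n_hemi, space.n_sources))
    labels = np.zeros(k_hemi * n_hemi, dtype=np.int64)
    blocks = {}
    col0 = 0
    for h, surf in enumerate(space.surfaces):
        theta, phi = _angles(surf.sphere.vertices)
        row = h * k_hemi
        row0 = row
        for l in range(l_max + 1):
            for m in range(-l, l + 1):
                T[row, col0:col0 + surf.n_vertices] = real_sph_harm(l, m, theta, phi)
                labels[row] = l
                row += 1
        blocks[surf.hemisphere] = (slice(row0, row), slice(col0, col0 + surf.n_vertices))
        col0 += surf.n_vertices
    return BasisSet(T, "harmonics", labels, blocks)


def abel_poisson_kernel(cos_gamma: np.ndarray, h: float) -> np.ndarray:
    """Closed form of the Abel-Poisson kernel on the sphere.

    K_h(cos g) = (1/4pi) (1-h^2) / (1 + h^2 - 2 h cos g)^(3/2)
               = sum_l (2l+1) h^l P_l(cos g) / 4pi,   0 < h < 1.
    """
    if not 0.0 < h < 1.0:
        raise ValueError("h must lie in (0, 1)")
    cg = np.clip(np.asarray(cos_gamma, dtype=float), -1.0, 1.0)
    return (1.0 - h**2) / (4.0 * np.pi * (1.0 + h**2 - 2.0 * h * cg) ** 1.5)


def default_spline_centers(space: SourceSpace, level: int = 2) -> list[np.ndarray]:
    """Per-hemisphere spline centre vertices: icosphere nodes snapped to mesh.

    Level-2 icosphere nodes (162) mapped to nearest sphere-mesh vertices give
    uniformly positioned centres aligned with actual dipoles.
    """
    nodes = icosphere(level).vertices
    centers = []
    for surf in space.surfaces:
        tree = cKDTree(surf.sphere.vertices)
        _, idx = tree.query(nodes)
        centers.append(np.unique(idx))
    return centers


def splines_T(space: SourceSpace, centers: list[np.ndarray] | None = None,
              h: float = 0.8) -> BasisSet:
    """Abel-Poisson spherical-spline basis, one row per centre vertex.

    Entry (k, j) is the kernel evaluated at the great-arc cosine between
    centre k and dipole j on the sphere map; entries are strictly positive
    and peak at the centre.  Default centres are the level-2 icosphere nodes
    snapped to the mesh (162 per hemisphere).
    """
    if not 0.0 < h < 1.0:
        raise ValueError("h must lie in (0, 1)")
    if centers is None:
        centers = default_spline_centers(space)
    if len(centers) != len(space.surfaces):
        raise ValueError("one centre set per hemisphere required")
    k_total = sum(len(c) for c in centers)
    T = np.zeros((k_total, space.n_sources))
    labels = np.zeros(k_total, dtype=np.int64)
    blocks = {}
    row0, col0 = 0, 0
    for surf, cen in zip(space.surfaces, centers):
        pos = surf.sphere.vertices
        cg = pos[np.asarray(cen)] @ pos.T
        T[row0:row0 + len(cen), col0:col0 + surf.n_vertices] = abel_poisson_kernel(cg, h)
        labels[row0:row0 + len(cen)] = np.asarray(cen)
        blocks[surf.hemisphere] = (slice(row0, row0 + len(cen)),
                                   slice(col0, col0 + surf.n_vertices))
        row0 += len(cen)
        col0 += surf.n_vertices
    return BasisSet(T, "splines", labels, blocks)


def identity_T(space: SourceSpace) -> BasisSet:
    """The single-dipole basis (T = I); downstream inverses reduce to MNE."""
    m = space.n_sources
    blocks = {}
    for surf, off in zip(space.surfaces, space.offsets):
        sl = slice(off, off + surf.n_vertices)
        blocks[surf.hemisphere] = (sl, sl)
    return BasisSet(np.eye(m), "dipole-identity", np.arange(m), blocks)


def nyquist_cutoff(n_sensors: int) -> int:
    """Spatial-Nyquist harmonic degree for a sensor net of ``n_sensors``.

    Returns the smallest degree L with L^2 >= n_sensors (so the harmonic
    count (L+1)^2 strictly exceeds the sensor count): a 128-channel net
    yields L = 12, i.e. 169 harmonics describing the scalp potential.
    """
    if n_sensors < 1:
        raise ValueError("n_sensors must be >= 1")
    return int(math.isqrt(n_sensors - 1)) + 1 if n_sensors > 1 else 1


# ----------------------------------------------------------------------------
# harmonic coefficient stream codec

_MAGIC = b"HEEGC1\n"


def encode_coefficients(coeffs: np.ndarray, basis: BasisSet,
                        precision: str = "float32") -> bytes:
    """Serialize per-sample harmonic coefficients as a compact stream.

    ``coeffs`` is (n_samples, K); for the default two-hemisphere constrained
    reconstruction at l_max = 10 that is 242 numbers per time sample.
    ``precision`` is ``float32`` (IEEE-754 little-endian) or ``int16``
    (scaled integers with a per-stream scale, 2 bytes per record).  Only the
    harmonic basis of an orientation-constrained solution is supported.
    """
    if basis.kind != "harmonics":
        raise ValueError("coefficient stream is defined for the harmonic basis only")
    x = np.atleast_2d(np.asarray(coeffs, dtype=float))
    if x.shape[1] != basis.K:
        raise ValueError(f"expected {basis.K} coefficients per sample")
    if precision == "float32":
        payload = x.astype("<f4").tobytes()
        scale = 1.0
    elif precision == "int16":
        peak = np.abs(x).max()
        scale = peak / 32767.0 if peak > 0 else 1.0
        payload = np.round(x / scale).astype("<i2").tobytes()
    else:
        raise ValueError("precision must be 'float32' or 'int16'")
    header = json.dumps({
        "n_samples": x.shape[0], "k": x.shape[1],
        "precision": precision, "scale": scale,
        "degrees": np.asarray(basis.labels).tolist(),
    }).encode()
    return _MAGIC + struct.pack("<I", len(header)) + header + payload


def decode_coefficients(stream: bytes) -> np.ndarray:
    """Inverse of :func:`encode_coefficients`; returns (n_samples, K)."""
    if not stream.startswith(_MAGIC):
        raise ValueError("not a coefficient stream")
    off = len(_MAGIC)
    (hlen,) = struct.unpack_from("<I", stream, off)
    off += 4
    header = json.loads(stream[off:off + hlen].decode())
    off += hlen
    shape = (header["n_samples"], header["k"])
    if header["precision"] == "float32":
        x = np.frombuffer(stream, dtype="<f4", offset=off).reshape(shape).astype(float)
    else:
        raw = np.frombuffer(stream, dtype="<i2", offset=off).reshape(shape)
        x = raw.astype(float) * header["scale"]
    return x


def save_basis(basis: BasisSet, path) -> None:
    """HDF5 export with per-row degree/centre labels and block structure."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("T", data=basis.T)
        d.attrs["kind"] = basis.kind
        f.create_dataset("labels", data=np.asarray(basis.labels))
        for hemi, (rows, cols) in basis.blocks.items():
            f.attrs[f"block_{hemi}"] = [rows.start, rows.stop, cols.start, cols.stop]


def load_basis(path) -> BasisSet:
    import h5py

    with h5py.File(path, "r") as f:
        t = f["T"][()]
        kind = f["T"].attrs["kind"]
        labels = f["labels"][()]
        blocks = {}
        for key in f.attrs:
            if key.startswith("block_"):
                r0, r1, c0, c1 = (int(x) for x in f.attrs[key])
                blocks[key[len("block_"):]] = (slice(r0, r1), slice(c0, c1))
    return BasisSet(t, str(kind), labels, blocks)


def coding_precision(precision: str, coeffs: np.ndarray) -> float:
    """Worst-case absolute round-trip error for a stream of ``coeffs``."""
    peak = float(np.abs(coeffs).max()) if np.asarray(coeffs).size else 0.0
    if precision == "float32":
        return peak * 2.0 ** -23 if peak else 0.0
    return (peak / 32767.0) / 2.0 + 1e-300 if peak else 0.0
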