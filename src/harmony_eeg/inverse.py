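"""Linear inverse operators for distributed EEG/MEG source estimation.

All algorithms share one Bayesian form.  With gain G, noise covariance C,
source prior R and regularization lambda, the posterior-mean operator is

    W = R G^T (G R G^T + lambda C)^-1 .

Choosing R in the single-dipole basis gives MNE (R = I), weighted MNE
(depth weights), LORETA (inverse surface-Laplacian smoothness) and IBF
(truncated Gaussian coherence).  Choosing a small global basis T and a
prior in that basis gives the harmonic/spline solutions: with Gt = G T^T,

    W = T^T R_b Gt^T (Gt R_b Gt^T + lambda C)^-1 ,

algebraically identical to the dipole-space prior R = T^T R_b T.  dSPM and
sLORETA are row rescalings of W; significance uses the noise variance
propagated through W.

The prior's overall scale is degenerate with lambda; diagonal priors are
normalized to unit mean diagonal and lambda multiplies C explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla
from scipy.stats import chi2

from .basis import BasisSet, harmonics_T, splines_T
from .forward import GainMatrix, NoiseCovariance
from .geometry import SourceSpace

__all__ = [
    "SourcePrior",
    "InverseOperator",
    "SourceEstimate",
    "linear_inverse",
    "basis_inverse",
    "harmony_prior",
    "depth_weights",
    "loreta_prior",
    "ibf_basis",
    "solution_noise_sd",
    "normalize",
    "f_threshold",
    "apply",
    "InverseFamily",
    "make_inverse_family",
]


@dataclass
class SourcePrior:
    """Source covariance prior in the active basis (diagonal, dense or implicit)."""

    kind: str
    weights: np.ndarray | None = None
    matrix: np.ndarray | None = None
    apply_fn: Callable[[np.ndarray], np.ndarray] | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ValueError("diagonal prior weights must be > 0")
            # scale degenerate with lambda: keep unit mean diagonal
            self.weights = self.weights / self.weights.mean()
        if self.matrix is not None:
            self.matrix = np.asarray(self.matrix, dtype=float)
            if not np.allclose(self.matrix, self.matrix.T, atol=1e-10 * max(1, np.abs(self.matrix).max())):
                raise ValueError("full prior must be symmetric")

    def apply(self, x: np.ndarray) -> np.ndarray:
        """R @ x without forming R when it is diagonal or implicit."""
        if self.weights is not None:
            return self.weights[:, None] * x
        if self.matrix is not None:
            return self.matrix @ x
        if self.apply_fn is not None:
            return self.apply_fn(x)
        return x  # identity


@dataclass
class InverseOperator:
    """Matrix W mapping sensor data to source amplitudes, plus its recipe."""

    W: np.ndarray
    algorithm: str
    lam: float
    orientation_mode: str = "constrained"
    normalization: str = "none"
    sigma: np.ndarray | None = None
    basis_kind: str = "dipole-identity"
    params: dict = field(default_factory=dict)

    @property
    def n_sources(self) -> int:
        k = 3 if self.orientation_mode == "free" else 1
        return self.W.shape[0] // k


@dataclass
class SourceEstimate:
    """Per-dipole amplitudes: signed scalars (constrained) or 3-vectors (free)."""

    values: np.ndarray
    orientation_mode: str = "constrained"
    mask: np.ndarray | None = None

    @property
    def magnitude(self) -> np.ndarray:
        if self.orientation_mode == "free":
            return np.linalg.norm(self.values, axis=1)
        return np.abs(self.values)


def _as_matrix(g) -> np.ndarray:
    return g.matrix if isinstance(g, GainMatrix) else np.asarray(g, dtype=float)


def _as_cov(c) -> np.ndarray:
    return c.matrix if isinstance(c, NoiseCovariance) else np.asarray(c, dtype=float)


def _sensor_solve(s_plus_lc: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve the symmetric sensor-space system, ridge-loading if singular."""
    try:
        return np.linalg.solve(s_plus_lc, rhs)
    except np.linalg.LinAlgError:
        ridge = 1e-10 * np.trace(s_plus_lc)
        loaded = s_plus_lc + ridge * np.eye(len(s_plus_lc))
        try:
            return np.linalg.solve(loaded, rhs)
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise np.linalg.LinAlgError(
                "sensor-space matrix singular even after ridge loading "
                f"(ridge {ridge:.3e}); check gain and covariance scaling") from err


def linear_inverse(G, C, R: SourcePrior | None = None, lam: float = 1.0,
                   algorithm: str = "mne") -> InverseOperator:
    """W = R G^T (G R G^T + lambda C)^-1 via a symmetric sensor-space solve."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    g = _as_matrix(G)
    c = _as_cov(C)
    prior = R or SourcePrior("identity")
    rgt = prior.apply(g.T)
    s = g @ rgt
    w = _sensor_solve((s + lam * c).T, rgt.T).T
    mode = G.orientation_mode if isinstance(G, GainMatrix) else "constrained"
    return InverseOperator(w, algorithm, lam, mode, params={"prior": prior.kind})


def basis_inverse(G, T: BasisSet, R_basis: SourcePrior | None = None,
                  C=None, lam: float = 1.0, algorithm: str = "basis") -> InverseOperator:
    """Inverse in a reduced basis: W = T^T R_b Gt^T (Gt R_b Gt^T + lam C)^-1."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    g = _as_matrix(G)
    if g.shape[1] != T.M:
        raise ValueError(f"gain has {g.shape[1]} columns but basis maps {T.M} dipoles")
    c = _as_cov(C)
    prior = R_basis or SourcePrior("identity")
    gt = g @ T.T.T  # n x K
    r_gt = prior.apply(gt.T)        # K x n
    rgt_dipole = T.T.T @ r_gt       # M x n = T^T R_b Gt^T
    s = gt @ r_gt
    w = _sensor_solve((s + lam * c).T, rgt_dipole.T).T
    mode = G.orientation_mode if isinstance(G, GainMatrix) else "constrained"
    return InverseOperator(w, algorithm, lam, mode, basis_kind=T.kind,
                           params={"prior": prior.kind})


# ----------------------------------------------------------------------------
# priors


def harmony_prior(basis: BasisSet, gamma: float = 0.75) -> SourcePrior:
    """Spectral prior suppressing high spatial frequencies.

    Harmonics: diagonal weight (1+l)^(-2*gamma) per (l, m) row, so degree-l
    content is shrunk progressively; gamma normally falls in 0.5-1 depending
    on how noisy the data are.  Splines: identity (smoothness is carried by
    the kernel scale h instead).
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if basis.kind == "harmonics":
        l = np.asarray(basis.labels, dtype=float)
        return SourcePrior("harmony-spectral", weights=(1.0 + l) ** (-2.0 * gamma),
                           params={"gamma": gamma})
    if basis.kind == "splines":
        return SourcePrior("identity", params={"gamma": gamma})
    raise ValueError("harmony prior is defined for harmonic or spline bases")


def depth_weights(G, exponent: float = 1.0) -> np.ndarray:
    """Per-dipole depth weights w_j = (sum_i g_ij^2)^(-exponent).

    Deeper dipoles produce weaker sensor patterns, so their gain columns are
    smaller and their prior variance larger.  Free-orientation gains pool the
    three columns of each dipole; the returned vector has one entry per gain
    column either way.
    """
    g = _as_matrix(G)
    col_power = (g**2).sum(axis=0)
    if isinstance(G, GainMatrix) and G.orientation_mode == "free":
        per_dip = col_power.reshape(-1, 3).sum(axis=1)
        col_power = np.repeat(per_dip, 3)
    bad = np.flatnonzero(col_power == 0)
    if bad.size:
        raise ValueError(f"gain column(s) {bad[:5].tolist()} have zero norm")
    return col_power ** (-float(exponent))


def _mesh_graph_laplacian(space: SourceSpace) -> sp.csr_matrix:
    """Block-diagonal discrete surface Laplacian (cotangent weights).

    Row sums are zero (L annihilates constants); combined with barycentric
    vertex areas (:func:`_vertex_areas`) it is a consistent Laplace-Beltrami
    discretization on the folded meshes.
    """
    blocks = []
    for surf in space.surfaces:
        p = surf.folded.vertices
        f = surf.folded.faces
        m = surf.n_vertices
        rows, cols, wts = [], [], []
        for k in range(3):
            i = f[:, k]
            j = f[:, (k + 1) % 3]
            o = f[:, (k + 2) % 3]
            e1 = p[i] - p[o]
            e2 = p[j] - p[o]
            cross = np.linalg.norm(np.cross(e1, e2), axis=1)
            cot = np.einsum("ij,ij->i", e1, e2) / np.maximum(cross, 1e-12)
            rows.extend([i, j])
            cols.extend([j, i])
            wts.extend([0.5 * cot, 0.5 * cot])
        a = sp.coo_matrix((np.concatenate(wts),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(m, m)).tocsr()
        n_comp, _ = csgraph.connected_components(a, directed=False)
        if n_comp != 1:
            raise ValueError("mesh is disconnected; Laplacian prior undefined")
        d = sp.diags(np.asarray(a.sum(axis=1)).ravel())
        blocks.append(d - a)
    return sp.block_diag(blocks, format="csc")


def _vertex_areas(space: SourceSpace) -> np.ndarray:
    """Barycentric vertex areas (mm^2) of the folded meshes, stacked."""
    out = []
    for surf in space.surfaces:
        p = surf.folded.vertices[surf.folded.faces]
        tri = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
        areas = np.zeros(surf.n_vertices)
        for k in range(3):
            np.add.at(areas, surf.folded.faces[:, k], tri / 3.0)
        out.append(areas)
    return np.concatenate(out)


def loreta_prior(space: SourceSpace, depth_w: np.ndarray | None = None,
                 ridge: float = 1e-8) -> SourcePrior:
    """Surface-LORETA smoothness prior R = D^(1/2) (L^T L + eps)^-1 D^(1/2).

    L is the 2-D graph Laplacian of the folded meshes (row sums zero), so the
    prior penalizes spatially rough solutions; D = diag(depth weights) gives
    deeper dipoles higher prior variance.  Applied implicitly through a
    sparse factorization - the dense inverse is never formed.
    """
    lap = _mesh_graph_laplacian(space)
    ltl = (lap.T @ lap).tocsc()
    eps = ridge * ltl.diagonal().mean()
    solver = spla.splu(ltl + eps * sp.identity(ltl.shape[0], format="csc"))
    sqrt_w = np.sqrt(depth_w) if depth_w is not None else np.ones(ltl.shape[0])

    def apply_fn(x: np.ndarray) -> np.ndarray:
        y = solver.solve(sqrt_w[:, None] * np.asarray(x, dtype=float))
        return sqrt_w[:, None] * y

    return SourcePrior("loreta-laplacian", apply_fn=apply_fn,
                       params={"ridge": ridge, "laplacian": lap})


def ibf_basis(space: SourceSpace, sigma: float = 10.0,
              k_per_hemi: int = 512) -> tuple[BasisSet, np.ndarray]:
    """Informed Basis Functions: leading eigenvectors of a Gaussian coherence.

    Per hemisphere, C_ij = exp(-d_ij^2 / 2 sigma^2) over folded-mesh geodesic
    distances (graph shortest paths); the basis rows are the top
    ``k_per_hemi`` eigenvectors and the returned weights are the matching
    eigenvalues, so T^T diag(w) T is the truncated coherence prior.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rows, labels, eigvals, blocks = [], [], [], {}
    row0, col0 = 0, 0
    m_total = space.n_sources
    for surf in space.surfaces:
        m = surf.n_vertices
        k = int(k_per_hemi)
        if k > m:
            raise ValueError(f"k_per_hemi={k} exceeds hemisphere size {m}")
        edges = surf.folded.edges()
        p = surf.folded.vertices
        lengths = np.linalg.norm(p[edges[:, 0]] - p[edges[:, 1]], axis=1)
        graph = sp.coo_matrix((np.r_[lengths, lengths],
                               (np.r_[edges[:, 0], edges[:, 1]],
                                np.r_[edges[:, 1], edges[:, 0]])), shape=(m, m)).tocsr()
        d = csgraph.dijkstra(graph, directed=False)
        coh = np.exp(-(d**2) / (2.0 * sigma**2))
        w, v = np.linalg.eigh(coh)
        order = np.argsort(w)[::-1][:k]
        block = np.zeros((k, m_total))
        block[:, col0:col0 + m] = v[:, order].T
        rows.append(block)
        labels.extend(range(k))
        eigvals.append(np.clip(w[order], 0.0, None))
        blocks[surf.hemisphere] = (slice(row0, row0 + k), slice(col0, col0 + m))
        row0 += k
        col0 += m
    basis = BasisSet(np.vstack(rows), "ibf", np.asarray(labels), blocks)
    return basis, np.concatenate(eigvals)


# ----------------------------------------------------------------------------
# noise propagation, normalization, thresholding


def solution_noise_sd(W: np.ndarray | InverseOperator, C,
                      orientation_mode: str | None = None) -> np.ndarray:
    """Per-source noise SD: sigma_j^2 = sum_ab W_ja C_ab W_jb.

    Free orientation sums the variances of the three components per dipole.
    """
    if isinstance(W, InverseOperator):
        orientation_mode = orientation_mode or W.orientation_mode
        W = W.W
    c = _as_cov(C)
    var = np.einsum("ia,ab,ib->i", W, c, W)
    if orientation_mode == "free":
        var = var.reshape(-1, 3).sum(axis=1)
    return np.sqrt(np.clip(var, 0.0, None))


def normalize(op: InverseOperator, method: str, G=None, C=None) -> InverseOperator:
    """dSPM / sLORETA row rescaling of an inverse operator.

    dSPM divides row j by the noise SD sigma_j propagated through W (the
    result is a Z-score map); sLORETA divides by the square root of the j-th
    diagonal of the model resolution matrix W G (free orientation: the trace
    of the 3x3 diagonal block).
    """
    if method not in ("dspm", "sloreta"):
        raise ValueError("method must be 'dspm' or 'sloreta'")
    if op.normalization != "none":
        raise ValueError("operator is already normalized")
    free = op.orientation_mode == "free"
    if method == "dspm":
        if C is None:
            raise ValueError("dSPM normalization needs the noise covariance")
        sigma = solution_noise_sd(op.W, C, op.orientation_mode)
        bad = np.flatnonzero(sigma <= 0)
        if bad.size:
            raise ValueError(f"non-positive noise SD at dipole(s) {bad[:5].tolist()}")
        scale = sigma
    else:
        if G is None:
            raise ValueError("sLORETA normalization needs the gain matrix")
        g = _as_matrix(G)
        res_diag = np.einsum("ij,ji->i", op.W, g)
        if free:
            res_diag = res_diag.reshape(-1, 3).sum(axis=1)  # 3x3 block trace
        bad = np.flatnonzero(res_diag <= 0)
        if bad.size:
            raise ValueError(f"non-positive resolution diagonal at dipole(s) {bad[:5].tolist()}")
        scale = np.sqrt(res_diag)
    w = op.W / np.repeat(scale, 3)[:, None] if free else op.W / scale[:, None]
    sigma_post = solution_noise_sd(w, C, op.orientation_mode) if C is not None else None
    return InverseOperator(w, op.algorithm, op.lam, op.orientation_mode,
                           normalization=method, sigma=sigma_post,
                           basis_kind=op.basis_kind, params=dict(op.params))


def f_threshold(values: np.ndarray, sigma: np.ndarray, alpha: float = 0.05,
                n_sensors: int = 128, orientation_mode: str = "constrained") -> np.ndarray:
    """Signal-to-noise significance mask, Bonferroni corrected over sensors.

    q_j = s_j^2 / sigma_j^2 (free orientation: ||s_j||^2 / sigma_j^2) is
    compared with the chi^2 quantile at 1 - alpha/n_sensors with 1 (or 3)
    degrees of freedom - the large-denominator limit of the F statistic.
    """
    values = np.asarray(values, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    if orientation_mode == "free":
        q = (values**2).sum(axis=1) / sigma**2
        dof = 3
    else:
        q = values**2 / sigma**2
        dof = 1
    threshold = chi2.ppf(1.0 - alpha / n_sensors, df=dof)
    return q > threshold


def apply(op: InverseOperator, v: np.ndarray) -> SourceEstimate:
    """Apply W to one sensor vector (or sensors x times array)."""
    v = np.asarray(v, dtype=float)
    if v.shape[0] != op.W.shape[1]:
        raise ValueError(f"data has {v.shape[0]} sensors, operator expects {op.W.shape[1]}")
    out = op.W @ v
    if op.orientation_mode == "free":
        out = out.reshape(-1, 3) if out.ndim == 1 else out.reshape(-1, 3, out.shape[-1])
    return SourceEstimate(out, op.orientation_mode)


def save_operator(op: InverseOperator, path) -> None:
    """HDF5 export of W with the full recipe (algorithm, lambda, basis,
    normalization, noise SDs) for provenance."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("W", data=op.W)
        d.attrs.update({"algorithm": op.algorithm, "lambda": op.lam,
                        "orientation_mode": op.orientation_mode,
                        "normalization": op.normalization,
                        "basis_kind": op.basis_kind})
        for k, v in op.params.items():
            if isinstance(v, (int, float, str)):
                d.attrs[f"param_{k}"] = v
        if op.sigma is not None:
            f.create_dataset("sigma", data=op.sigma)


def load_operator(path) -> InverseOperator:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["W"]
        params = {k[len("param_"):]: d.attrs[k] for k in d.attrs if k.startswith("param_")}
        return InverseOperator(
            d[()], str(d.attrs["algorithm"]), float(d.attrs["lambda"]),
            str(d.attrs["orientation_mode"]), str(d.attrs["normalization"]),
            f["sigma"][()] if "sigma" in f else None,
            str(d.attrs["basis_kind"]), params)


# ----------------------------------------------------------------------------
# lambda families (shared precomputation across regularization values)


class InverseFamily:
    """One algorithm's inverse operators over the regularization axis.

    Precomputes R G^T (M x n) and the sensor-space matrix S = G R G^T once;
    each lambda then costs a single n x n symmetric solve.  Also provides the
    sensor resolution matrix A(lambda) = S (S + lambda C)^-1 used by OCV.
    """

    def __init__(self, rgt: np.ndarray, s: np.ndarray, c: np.ndarray,
                 algorithm: str, orientation_mode: str = "constrained",
                 basis_kind: str = "dipole-identity", params: dict | None = None):
        self.rgt = rgt
        self.s = 0.5 * (s + s.T)
        self.c = c
        self.algorithm = algorithm
        self.orientation_mode = orientation_mode
        self.basis_kind = basis_kind
        self.params = params or {}

    @property
    def n_sensors(self) -> int:
        return self.s.shape[0]

    def operator(self, lam: float) -> InverseOperator:
        if lam <= 0:
            raise ValueError("lam must be > 0")
        w = _sensor_solve((self.s + lam * self.c).T, self.rgt.T).T
        return InverseOperator(w, self.algorithm, lam, self.orientation_mode,
                               basis_kind=self.basis_kind, params=dict(self.params))

    def resolution(self, lam: float) -> np.ndarray:
        """Sensor-space resolution matrix A = G W at this lambda."""
        if lam <= 0:
            raise ValueError("lam must be > 0")
        return _sensor_solve((self.s + lam * self.c).T, self.s.T).T

    def default_lambda_scale(self) -> float:
        """Scale-free anchor trace(G R G^T) / trace(C) / n for lambda grids."""
        return float(np.trace(self.s) / np.trace(self.c) / self.n_sensors)


def make_inverse_family(algorithm: str, G, C, space: SourceSpace | None = None,
                        l_max: int = 10, gamma: float = 0.75, h: float = 0.8,
                        depth_exponent: float = 1.0, ibf_sigma: float = 10.0,
                        ibf_k: int = 512, basis: BasisSet | None = None) -> InverseFamily:
    """Assemble the prior/basis recipe for a named algorithm.

    Recognized: ``harmony`` (harmonics + spectral prior), ``splines``,
    ``mne``, ``wmne``, ``loreta``, ``ibf``; ``dspm``/``sloreta`` build the
    MNE family (their normalization is applied to the finished operator).
    """
    g = _as_matrix(G)
    c = _as_cov(C)
    mode = G.orientation_mode if isinstance(G, GainMatrix) else "constrained"
    name = algorithm.lower()
    params = {}

    if name in ("harmony", "hrm", "splines", "spl"):
        if basis is None:
            if space is None:
                raise ValueError("harmony/splines need the source space (or an explicit basis)")
            if mode == "free":
                raise ValueError("basis algorithms are implemented for constrained orientation")
            basis = harmonics_T(space, l_max) if name in ("harmony", "hrm") else splines_T(space, h=h)
        prior = harmony_prior(basis, gamma)
        gt = g @ basis.T.T
        r_gt = prior.apply(gt.T)
        rgt = basis.T.T @ r_gt
        s = gt @ r_gt
        params = {"gamma": gamma, "l_max": l_max} if basis.kind == "harmonics" else {"h": h}
        return InverseFamily(rgt, s, c, name, mode, basis.kind, params)

    if name in ("mne", "dspm", "sloreta"):
        rgt = g.T.copy()
        return InverseFamily(rgt, g @ rgt, c, name, mode)

    if name == "wmne":
        w = depth_weights(G if isinstance(G, GainMatrix) else g, depth_exponent)
        w = w / w.mean()
        rgt = w[:, None] * g.T
        return InverseFamily(rgt, g @ rgt, c, name, mode, params={"depth_exponent": depth_exponent})

    if name in ("loreta", "lrt"):
        if space is None:
            raise ValueError("loreta needs the source space")
        if mode == "free":
            raise ValueError("surface LORETA is implemented for constrained orientation")
        dw = depth_weights(G if isinstance(G, GainMatrix) else g, depth_exponent)
        prior = loreta_prior(space, dw)
        rgt = prior.apply(g.T)
        return InverseFamily(rgt, g @ rgt, c, name, mode,
                             params={"depth_exponent": depth_exponent})

    if name == "ibf":
        if space is None:
            raise ValueError("ibf needs the source space")
        if mode == "free":
            raise ValueError("IBF is implemented for constrained orientation")
        k = min(ibf_k, min(s_.n_vertices for s_ in space.surfaces))
        bset, eig = ibf_basis(space, ibf_sigma, k)
        dw = np.sqrt(depth_weights(G if isinstance(G, GainMatrix) else g, depth_exponent))
        t_eff = bset.T * dw[None, :]
        prior_w = np.clip(eig, 1e-12 * eig.max(), None)
        prior_w = prior_w / prior_w.mean()
        gt = g @ t_eff.T
        r_gt = prior_w[:, None] * gt.T
        rgt = t_eff.T @ r_gt
        s = gt @ r_gt
        return InverseFamily(rgt, s, c, name, mode, "ibf",
                             params={"sigma": ibf_sigma, "k_per_hemi": k})

    raise ValueError(f"unknown algorithm {algorithm!r}")
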