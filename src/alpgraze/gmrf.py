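"""Intrinsic Gaussian Markov random field structures.

Two difference-penalty priors are used for the structured random effects of
the activity regressions:

* a first-order random walk (RW1) over elevation bins — penalty on first
  differences, rank deficiency 1 (constants are free);
* a two-dimensional second-order random walk (RW2) over the lattice of
  active grid cells — penalty ``sum(f_xx^2 + 2 f_xy^2 + f_yy^2)`` assembled
  from second-difference operators with free boundaries, which approximates
  a thin-plate spline.  On a full rectangle its interior rows realise the
  13-point stencil (centre 20, cardinal -8, diagonal 2, second-order
  cardinal 1) and the null space is spanned by {1, x, y}.

Because the structure matrices are improper (rank deficient), models using
them attach linear constraints (sum-to-zero, and orthogonality to the x/y
coordinate vectors for the planar RW2), and the unit-precision structure is
*scaled* so that the geometric mean of the marginal variances of the
constrained generalised inverse equals 1.  Scaling makes a Gamma(a, b) prior
on the precision mean the same thing for every effect: (a, b) then determine
the upper limit U of the marginal standard deviation at a fixed tail
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import gamma as gamma_dist


@dataclass
class PrecisionStructure:
    """Sparse intrinsic-GMRF structure matrix with its constraints.

    Attributes
    ----------
    Q
        Symmetric positive semi-definite structure matrix (unit precision),
        CSR format.
    rank_deficiency
        Dimension of the null space of ``Q``.
    constraints
        Dense ``k x n`` matrix ``A``; models condition on ``A f = 0``.
    scaling
        Cumulative factor the structure matrix has been multiplied by; 1.0
        for an unscaled structure.  After :func:`scale_precision` the
        geometric mean of the constrained generalised-inverse marginal
        variances is 1.
    """

    Q: sp.csr_matrix
    rank_deficiency: int
    constraints: np.ndarray
    scaling: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.Q.shape[0]


def build_rw1_precision(n: int) -> PrecisionStructure:
    """First-order random-walk structure on ``n`` ordered bins.

    ``Q = D1' D1`` for the first-difference operator ``D1``; tridiagonal with
    1/2 on the diagonal ends/interior and -1 off-diagonal.  Rank deficiency 1
    (constants), sum-to-zero constraint attached.
    """
    if n < 2:
        raise ValueError("RW1 needs at least 2 bins")
    data = np.ones(n - 1)
    D1 = sp.diags([-data, data], offsets=[0, 1], shape=(n - 1, n), format="csr")
    Q = (D1.T @ D1).tocsr()
    A = np.ones((1, n))
    return PrecisionStructure(Q=Q, rank_deficiency=1, constraints=A, meta={"kind": "rw1"})


def _second_difference_ops(active: np.ndarray):
    """Second-difference operators Dxx, Dyy, Dxy restricted to active cells.

    Rows exist only where the full difference stencil lies inside the active
    mask (free boundary: no phantom cells outside)."""
    nrows, ncols = active.shape
    idx = -np.ones(active.shape, dtype=int)
    idx[active] = np.arange(active.sum())

    rows_xx, cols_xx, vals_xx = [], [], []
    rows_yy, cols_yy, vals_yy = [], [], []
    rows_xy, cols_xy, vals_xy = [], [], []
    k_xx = k_yy = k_xy = 0
    for i in range(nrows):
        for j in range(ncols):
            if not active[i, j]:
                continue
            # d^2/dx^2 centred at (i, j)
            if 0 < j < ncols - 1 and active[i, j - 1] and active[i, j + 1]:
                rows_xx += [k_xx] * 3
                cols_xx += [idx[i, j - 1], idx[i, j], idx[i, j + 1]]
                vals_xx += [1.0, -2.0, 1.0]
                k_xx += 1
            # d^2/dy^2
            if 0 < i < nrows - 1 and active[i - 1, j] and active[i + 1, j]:
                rows_yy += [k_yy] * 3
                cols_yy += [idx[i - 1, j], idx[i, j], idx[i + 1, j]]
                vals_yy += [1.0, -2.0, 1.0]
                k_yy += 1
            # mixed difference on the 2x2 block anchored at (i, j)
            if i < nrows - 1 and j < ncols - 1 and active[i + 1, j] and active[i, j + 1] and active[i + 1, j + 1]:
                rows_xy += [k_xy] * 4
                cols_xy += [idx[i, j], idx[i, j + 1], idx[i + 1, j], idx[i + 1, j + 1]]
                vals_xy += [1.0, -1.0, -1.0, 1.0]
                k_xy += 1
    n = int(active.sum())
    Dxx = sp.csr_matrix((vals_xx, (rows_xx, cols_xx)), shape=(k_xx, n))
    Dyy = sp.csr_matrix((vals_yy, (rows_yy, cols_yy)), shape=(k_yy, n))
    Dxy = sp.csr_matrix((vals_xy, (rows_xy, cols_xy)), shape=(k_xy, n))
    return Dxx, Dyy, Dxy


def _mask_connected(active: np.ndarray) -> bool:
    from scipy.ndimage import label

    _, ncomp = label(active)
    return ncomp <= 1


def build_rw2d_precision(active: np.ndarray) -> PrecisionStructure:
    """Planar second-order random-walk structure over an active-cell mask.

    ``Q = Dxx'Dxx + Dyy'Dyy + 2 Dxy'Dxy`` with free boundaries.  Constraints:
    sum-to-zero and orthogonality to the (centred) x and y coordinate
    vectors; rank deficiency 3 on a full rectangle.
    """
    active = np.asarray(active, dtype=bool)
    if active.ndim != 2 or min(active.shape) < 4:
        raise ValueError("active mask must be 2-D with at least 4x4 extent")
    if not _mask_connected(active):
        raise ValueError("active mask is disconnected")
    Dxx, Dyy, Dxy = _second_difference_ops(active)
    Q = (Dxx.T @ Dxx + Dyy.T @ Dyy + 2.0 * (Dxy.T @ Dxy)).tocsr()

    rows, cols = np.nonzero(active)
    x = cols - cols.mean()
    y = rows - rows.mean()
    A = np.vstack([np.ones_like(x, dtype=float), x.astype(float), y.astype(float)])
    return PrecisionStructure(Q=Q, rank_deficiency=3, constraints=A, meta={"kind": "rw2d", "shape": active.shape})


def constrained_marginal_variances(struct: PrecisionStructure, jitter_rel: float = 1e-8) -> np.ndarray:
    """Diagonal of the constrained generalised inverse of the structure matrix.

    Computed densely: invert the jittered structure and apply the conditioning
    (kriging) correction for the linear constraints.  Intended for structure
    sizes up to a few thousand cells.
    """
    Q = struct.Q.toarray()
    n = Q.shape[0]
    delta = jitter_rel * np.max(Q.diagonal())
    Sigma = np.linalg.inv(Q + delta * np.eye(n))
    A = struct.constraints
    if A is not None and A.size:
        SA = Sigma @ A.T
        M = A @ SA
        Sigma = Sigma - SA @ np.linalg.solve(M, SA.T)
    return np.clip(np.diag(Sigma), 0.0, None)


def scale_precision(struct: PrecisionStructure) -> PrecisionStructure:
    """Scale a structure so its reference (geometric-mean) marginal SD is 1.

    Multiplies ``Q`` by the geometric mean of the constrained
    generalised-inverse marginal variances; idempotent up to numerical
    tolerance.
    """
    var = constrained_marginal_variances(struct)
    if np.any(var <= 0):
        raise ValueError("constrained structure is numerically singular")
    gmean = float(np.exp(np.mean(np.log(var))))
    return PrecisionStructure(
        Q=(struct.Q * gmean).tocsr(),
        rank_deficiency=struct.rank_deficiency,
        constraints=struct.constraints,
        scaling=struct.scaling * gmean,
        meta=dict(struct.meta),
    )


def sample_constrained(struct: PrecisionStructure, tau: float, rng: np.random.Generator, jitter_rel: float = 1e-8) -> np.ndarray:
    """Draw one realisation of the constrained intrinsic field with precision
    ``tau * Q``.

    Dense Cholesky sampling of the jittered precision followed by a kriging
    correction onto the constraint surface ``A f = 0``; intended for fields
    up to a few thousand cells.
    """
    if tau <= 0:
        raise ValueError("precision must be positive")
    Q = struct.Q.toarray() * tau
    n = Q.shape[0]
    delta = jitter_rel * np.max(Q.diagonal())
    Q += delta * np.eye(n)
    L = np.linalg.cholesky(Q)
    z = rng.standard_normal(n)
    x = np.linalg.solve(L.T, z)  # x ~ N(0, Q^-1)
    A = struct.constraints
    if A is not None and A.size:
        QA = np.linalg.solve(Q, A.T)
        M = A @ QA
        x = x - QA @ np.linalg.solve(M, A @ x)
    return x


def prior_sd_upper_limit(a: float, b: float, tail: float = 0.001) -> float:
    """Upper limit U of the marginal SD implied by a Gamma(a, b) precision prior.

    For precision ``tau ~ Gamma(shape a, rate b)`` applied to a scaled
    structure (reference SD 1), U solves ``P(tau^{-1/2} > U) = tail``, i.e.
    ``U = 1 / sqrt(Q_Gamma(tail))`` with the Gamma quantile at the lower tail.
    For ``a = 1`` this reduces to ``sqrt(b / (-log(1 - tail)))``.
    """
    if a <= 0 or b <= 0:
        raise ValueError("Gamma prior parameters must be positive")
    q = gamma_dist.ppf(tail, a, scale=1.0 / b)
    return float(1.0 / np.sqrt(q))
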