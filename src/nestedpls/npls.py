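"""Tri-linear two-block PLS regression core.

Latent variables (LVs) are extracted iteratively from the unfolded arrays:
starting from the leading principal component of the dependent residual as
``u``, the loop alternates

    w = X^T u,  t = X w,  q = Y^T t,  u = Y q

with ``w`` and ``q`` normalized to unit length after each back-projection,
until the change in ``||t||`` between sweeps drops below tolerance.  Each LV
is removed from the residuals before the next one is extracted: ``X`` loses
``t w^T`` and ``Y`` loses ``b t q^T`` with the scalar inner coefficient
``b = (t^T t)^{-1} t^T u``.  The full inner regression matrix
``B = (T^T T)^{-1} T^T U`` is also computed and reported; predictions use the
per-LV scalar coefficients, which makes training predictions agree exactly
with the deflation residual and keeps residual norms monotone.

Combined weights live on the unfolded (time * variable) axis with the
variable index fastest; the same order is used by every reshape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .dataset import TensorPair

__all__ = [
    "FitSettings",
    "LatentVariable",
    "NPLSModel",
    "NPLSError",
    "unfold",
    "refold",
    "extract_latent_variable",
    "inner_regression",
    "deflate",
    "fit",
    "predict",
]


class NPLSError(ValueError):
    pass


def unfold(tensor: np.ndarray) -> np.ndarray:
    """Matricize an i x j x k array into i x (j*k), variable index fastest."""
    arr = np.asarray(tensor)
    if arr.ndim != 3:
        raise NPLSError(f"expected a 3-way array, got ndim={arr.ndim}")
    i, j, k = arr.shape
    return arr.reshape(i, j * k)


def refold(matrix: np.ndarray, n_times: int, n_vars: int) -> np.ndarray:
    """Inverse of :func:`unfold`."""
    mat = np.asarray(matrix)
    if mat.ndim != 2 or mat.shape[1] != n_times * n_vars:
        raise NPLSError(
            f"cannot refold shape {mat.shape} into (*, {n_times}, {n_vars})"
        )
    return mat.reshape(mat.shape[0], n_times, n_vars)


@dataclass(frozen=True)
class FitSettings:
    n_lvs: int
    tol: float = 1e-10
    max_iterations: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lvs < 0:
            raise NPLSError("n_lvs must be >= 0")
        if self.tol <= 0:
            raise NPLSError("tol must be > 0")
        if self.max_iterations < 1:
            raise NPLSError("max_iterations must be >= 1")


@dataclass
class LatentVariable:
    """One extracted component; ``index`` is 1-based."""

    index: int
    t: np.ndarray
    u: np.ndarray
    w: np.ndarray
    w_time: np.ndarray
    w_var: np.ndarray
    q: np.ndarray
    q_time: np.ndarray
    q_var: np.ndarray
    iterations_used: int
    converged: bool
    w_factor_residual: float
    q_factor_residual: float

    def flipped(self) -> "LatentVariable":
        """The sign-negated twin (predictions are unchanged by the flip)."""
        return LatentVariable(
            index=self.index, t=-self.t, u=-self.u,
            w=-self.w, w_time=-self.w_time, w_var=self.w_var,
            q=-self.q, q_time=-self.q_time, q_var=self.q_var,
            iterations_used=self.iterations_used, converged=self.converged,
            w_factor_residual=self.w_factor_residual,
            q_factor_residual=self.q_factor_residual,
        )


def _rank1_factor(w: np.ndarray, n_times: int, n_vars: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Leading singular-vector factorization of the reshaped combined weight.

    Returns (time part, variable part, relative residual); the variable part
    is unit norm with its largest-magnitude entry positive, and
    outer(time, variable) approximates the reshaped weight.
    """
    mat = w.reshape(n_times, n_vars)
    uu, ss, vt = np.linalg.svd(mat, full_matrices=False)
    w_time = uu[:, 0] * ss[0]
    w_var = vt[0]
    peak = np.argmax(np.abs(w_var))
    if w_var[peak] < 0:
        w_var = -w_var
        w_time = -w_time
    approx = np.outer(w_time, w_var)
    denom = np.linalg.norm(mat)
    resid = float(np.linalg.norm(mat - approx) / denom) if denom > 0 else 0.0
    return w_time, w_var, resid


def extract_latent_variable(
    X_res: np.ndarray,
    Y_res: np.ndarray,
    shape_x: tuple[int, int],
    shape_y: tuple[int, int],
    settings: FitSettings,
    rng: np.random.Generator,
    index: int = 1,
) -> LatentVariable:
    """Extract one LV from unfolded residual matrices (not modified in place)."""
    if X_res.shape[0] != Y_res.shape[0]:
        raise NPLSError("X and Y residuals must share the first dimension")
    if np.linalg.norm(X_res) == 0 or np.linalg.norm(Y_res) == 0:
        raise NPLSError("no variance left to model")

    # u initialized from the leading principal component of the Y residual;
    # t randomly initialized (only the first convergence check depends on it)
    uu, ss, _ = np.linalg.svd(Y_res, full_matrices=False)
    u = uu[:, 0] * ss[0]
    t_prev = rng.standard_normal(X_res.shape[0])

    converged = False
    iterations = 0
    for iterations in range(1, settings.max_iterations + 1):
        w = X_res.T @ u
        nw = np.linalg.norm(w)
        if nw == 0:
            raise NPLSError("degenerate weight update (w == 0)")
        w /= nw
        t = X_res @ w
        q = Y_res.T @ t
        nq = np.linalg.norm(q)
        if nq == 0:
            raise NPLSError("degenerate weight update (q == 0)")
        q /= nq
        u = Y_res @ q
        if abs(np.linalg.norm(t) - np.linalg.norm(t_prev)) <= settings.tol:
            converged = True
            break
        t_prev = t

    w_time, w_var, w_resid = _rank1_factor(w, *shape_x)
    q_time, q_var, q_resid = _rank1_factor(q, *shape_y)
    return LatentVariable(
        index=index, t=t, u=u, w=w, w_time=w_time, w_var=w_var,
        q=q, q_time=q_time, q_var=q_var,
        iterations_used=iterations, converged=converged,
        w_factor_residual=w_resid, q_factor_residual=q_resid,
    )


def inner_regression(T: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Least-squares coefficients mapping accumulated t-scores to u-scores.

    Returns an n x n matrix (a 1 x 1 matrix for a single LV).  Raises on a
    rank-deficient score matrix, which signals a degenerate resample draw.
    """
    T = np.atleast_2d(np.asarray(T, dtype=float))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if T.ndim != 2 or U.ndim != 2 or T.shape[0] != U.shape[0]:
        raise NPLSError("T and U must be matrices with matching rows")
    gram = T.T @ T
    if np.linalg.matrix_rank(gram, tol=1e-12 * max(1.0, float(np.trace(gram)))) < gram.shape[0]:
        raise NPLSError("rank-deficient score matrix in inner regression")
    return np.linalg.solve(gram, T.T @ U)


def deflate(
    X_res: np.ndarray, Y_res: np.ndarray, lv: LatentVariable, b: float
) -> tuple[np.ndarray, np.ndarray]:
    """Remove one LV's contribution from the unfolded residuals."""
    X_new = X_res - np.outer(lv.t, lv.w)
    Y_new = Y_res - b * np.outer(lv.t, lv.q)
    return X_new, Y_new


@dataclass
class NPLSModel:
    latent_variables: list[LatentVariable]
    b: np.ndarray  # per-LV scalar inner coefficients, length n
    B: np.ndarray  # full (T^T T)^{-1} T^T U inner matrix, n x n
    X_residual: np.ndarray  # i x j x k after final deflation
    Y_residual: np.ndarray  # i x l x m after final deflation
    x_shape: tuple[int, int]  # (j, k)
    y_shape: tuple[int, int]  # (l, m)
    settings: FitSettings
    x_residual_norms: list[float] = field(default_factory=list)  # per LV count 0..n
    y_residual_norms: list[float] = field(default_factory=list)
    residual_exhausted: bool = False  # fewer LVs than requested were extractable

    @property
    def n_lvs(self) -> int:
        return len(self.latent_variables)

    @property
    def T(self) -> np.ndarray:
        return np.column_stack([lv.t for lv in self.latent_variables])

    @property
    def U(self) -> np.ndarray:
        return np.column_stack([lv.u for lv in self.latent_variables])

    @property
    def W(self) -> np.ndarray:
        return np.column_stack([lv.w for lv in self.latent_variables])

    @property
    def Q(self) -> np.ndarray:
        return np.column_stack([lv.q for lv in self.latent_variables])

    def to_json(self) -> str:
        def lv_dict(lv: LatentVariable) -> dict:
            d = asdict(lv)
            return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}

        payload = {
            "settings": asdict(self.settings),
            "x_shape": list(self.x_shape),
            "y_shape": list(self.y_shape),
            "b": self.b.tolist(),
            "B": self.B.tolist(),
            "x_residual_norms": self.x_residual_norms,
            "y_residual_norms": self.y_residual_norms,
            "latent_variables": [lv_dict(lv) for lv in self.latent_variables],
        }
        return json.dumps(payload, indent=1)


def fit(X: np.ndarray, Y: np.ndarray, settings: FitSettings) -> NPLSModel:
    """Fit an N-PLS model on standardized i x j x k and i x l x m tensors."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 3 or Y.ndim != 3:
        raise NPLSError("fit expects 3-way arrays")
    if X.shape[0] != Y.shape[0]:
        raise NPLSError("X and Y must share the first (condition) dimension")
    i, j, k = X.shape
    _, l, m = Y.shape
    Xu = unfold(X).copy()
    Yu = unfold(Y).copy()
    rng = np.random.default_rng(settings.seed)

    lvs: list[LatentVariable] = []
    bs: list[float] = []
    x_norms = [float(np.linalg.norm(Xu))]
    y_norms = [float(np.linalg.norm(Yu))]
    exhausted = False
    for n in range(1, settings.n_lvs + 1):
        # stop early once a residual is numerically exhausted (further LVs
        # would only decompose round-off and break the inner regression)
        if n > 1 and (
            x_norms[-1] <= 1e-12 * x_norms[0] or y_norms[-1] <= 1e-12 * y_norms[0]
        ):
            exhausted = True
            break
        lv = extract_latent_variable(
            Xu, Yu, (j, k), (l, m), settings, rng, index=n
        )
        tt = float(lv.t @ lv.t)
        if tt == 0:
            raise NPLSError(f"zero score vector at LV {n}")
        b = float(lv.t @ lv.u) / tt
        Xu, Yu = deflate(Xu, Yu, lv, b)
        lvs.append(lv)
        bs.append(b)
        x_norms.append(float(np.linalg.norm(Xu)))
        y_norms.append(float(np.linalg.norm(Yu)))

    if lvs:
        T = np.column_stack([lv.t for lv in lvs])
        U = np.column_stack([lv.u for lv in lvs])
        B = inner_regression(T, U)
    else:
        B = np.zeros((0, 0))
    return NPLSModel(
        latent_variables=lvs,
        b=np.array(bs),
        B=B,
        X_residual=refold(Xu, j, k),
        Y_residual=refold(Yu, l, m),
        x_shape=(j, k),
        y_shape=(l, m),
        settings=settings,
        x_residual_norms=x_norms,
        y_residual_norms=y_norms,
        residual_exhausted=exhausted,
    )


def predict(model: NPLSModel, X_new: np.ndarray, n_lvs_used: int | None = None) -> np.ndarray:
    """Predict standardized Y for new standardized X slabs.

    New condition scores are obtained by sequentially projecting the new
    residuals onto each LV's combined weight (with matching deflation);
    the dependent block is rebuilt from the per-LV inner coefficients.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 3 or X_new.shape[1:] != model.x_shape:
        raise NPLSError(
            f"X_new shape {X_new.shape} does not match training grids {model.x_shape}"
        )
    n = model.n_lvs if n_lvs_used is None else int(n_lvs_used)
    if n > model.n_lvs:
        raise NPLSError(f"n_lvs_used={n} exceeds fitted LV count {model.n_lvs}")
    l, m = model.y_shape
    Xu = unfold(X_new).copy()
    Yu_hat = np.zeros((X_new.shape[0], l * m))
    for idx in range(n):
        lv = model.latent_variables[idx]
        t_new = Xu @ lv.w
        Xu -= np.outer(t_new, lv.w)
        Yu_hat += model.b[idx] * np.outer(t_new, lv.q)
    return refold(Yu_hat, l, m)
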