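"""Modified multiblock PLS: fit, predict, and implied regression coefficients.

The model extracts R latent components from a blocked, autoscaled predictor
matrix X = [X(1) | ... | X(C)] and a centred response y.  Per component r:

* within-block weights  u_r(c) = E(c)' f / ||E(c)' f||            (unit norm)
* within-block scores   s_r(c) = E(c) u_r(c)
* super-score design    S_r = [ s_r(1)/l(1) | ... | s_r(C)/l(C) ]
* super-weights         w_r = S_r' f / ||S_r' f||                 (unit norm)
* super-score           t_r = S_r w_r
* loadings              p_r = E' t_r / (t_r' t_r),  q_r = f' t_r / (t_r' t_r)
* deflation             E <- E - t_r p_r',  f <- f - t_r q_r

where E starts at X, f at y, and l(c) is the number of variables in block c.
The division of each block score by its block size l(c) is the modification
that stops large blocks from dominating the super-score; the same
normalization is applied at prediction time so that predicting the training
data reproduces the fitted values exactly.  With a single block the model is
algebraically identical to ordinary PLS1 (orthogonal-scores NIPALS): the
1/l factor cancels through p_r and q_r.

The per-component covariances cov(y, t_r) stored on the model feed the
block-importance statistics (BIP/BwIP); by default they are taken against
the original centred response rather than the running residual (a switch
selects the residual convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocking import BlockPartition
from .io import Dataset, ScalingParams, apply_scaling, invert_scaling

__all__ = [
    "FitOptions",
    "MbplsModel",
    "fit_mbpls",
    "predict",
    "predict_components",
    "fitted_coefficients",
]


@dataclass
class FitOptions:
    """Fit controls: component count, degeneracy tolerance, normalization switches."""

    n_components: int = 2
    tol: float = 1e-12  # on squared norms
    block_size_normalization: bool = True
    cov_target: str = "y"  # "y" or "residual"

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.cov_target not in ("y", "residual"):
            raise ValueError("cov_target must be 'y' or 'residual'")


@dataclass
class MbplsModel:
    """Fitted multiblock PLS model.

    ``U`` holds one (p_c, R) within-block weight matrix per block, ``W`` the
    (C, R) super-weights, ``P`` the (p, R) X-loadings, ``q`` the R response
    loadings, ``T`` the (n, R) training super-scores and ``cov_yt`` the R
    per-component covariances with the response.  ``n_components`` is the
    effective component count actually extracted (deflation can exhaust the
    signal before the requested count is reached).
    """

    partition: BlockPartition
    U: list[np.ndarray]
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    cov_yt: np.ndarray
    variable_ids: list[str]
    n_components_requested: int
    block_size_normalization: bool = True
    scaling: ScalingParams | None = None
    response_name: str = "y"

    @property
    def n_components(self) -> int:
        return int(self.W.shape[1])

    @property
    def n_blocks(self) -> int:
        return self.partition.n_blocks

    @property
    def p(self) -> int:
        return self.partition.p

    @property
    def block_sizes(self) -> np.ndarray:
        return self.partition.block_sizes

    def to_dict(self) -> dict:
        return {
            "labels": self.partition.labels.tolist(),
            "U": [u.tolist() for u in self.U],
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "T": self.T.tolist(),
            "cov_yt": self.cov_yt.tolist(),
            "variable_ids": list(self.variable_ids),
            "n_components_requested": self.n_components_requested,
            "block_size_normalization": self.block_size_normalization,
            "scaling": None if self.scaling is None else self.scaling.to_dict(),
            "response_name": self.response_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MbplsModel":
        return cls(
            partition=BlockPartition(labels=np.array(d["labels"], dtype=int)),
            U=[np.array(u, dtype=float) for u in d["U"]],
            W=np.array(d["W"], dtype=float),
            P=np.array(d["P"], dtype=float),
            q=np.array(d["q"], dtype=float),
            T=np.array(d["T"], dtype=float),
            cov_yt=np.array(d["cov_yt"], dtype=float),
            variable_ids=list(d["variable_ids"]),
            n_components_requested=int(d["n_components_requested"]),
            block_size_normalization=bool(d["block_size_normalization"]),
            scaling=None
            if d.get("scaling") is None
            else ScalingParams.from_dict(d["scaling"]),
            response_name=d.get("response_name", "y"),
        )


def fit_mbpls(
    ds: Dataset,
    partition: BlockPartition,
    opts: FitOptions | None = None,
    scaling: ScalingParams | None = None,
) -> MbplsModel:
    """Fit the modified multiblock PLS on an already-autoscaled Dataset.

    ``ds.X`` must have centred, unit-sd columns and ``ds.y`` must be centred
    (the usual route is :func:`blockpls.io.autoscale`).  ``scaling`` attaches
    the training parameters so :func:`predict` can consume raw data.  If a
    block's weight vector degenerates (zero covariance with the residual) it
    contributes nothing at that component; if every block degenerates, or
    the super-score collapses, extraction stops early and the effective
    component count is recorded.
    """
    opts = opts or FitOptions()
    if ds.y is None:
        raise ValueError("dataset has no response")
    X = ds.X
    y = ds.y
    n, p = X.shape
    if partition.p != p:
        raise ValueError("partition does not cover the dataset's variables")
    r_max = min(opts.n_components, n - 1, p)
    blocks = partition.blocks()
    sizes = partition.block_sizes.astype(float)
    c_count = len(blocks)

    E = X.copy()
    f = y.copy()
    y0 = y - y.mean()

    U_cols: list[list[np.ndarray]] = [[] for _ in range(c_count)]
    W_cols, P_cols, q_vals, T_cols, cov_vals = [], [], [], [], []

    for _ in range(r_max):
        S = np.zeros((n, c_count))
        u_this = []
        any_nonzero = False
        for c, idx in enumerate(blocks):
            z = E[:, idx].T @ f
            nz2 = float(z @ z)
            if nz2 <= opts.tol:
                u = np.zeros(idx.size)
            else:
                u = z / np.sqrt(nz2)
                any_nonzero = True
            u_this.append(u)
            s = E[:, idx] @ u
            S[:, c] = s / sizes[c] if opts.block_size_normalization else s
        if not any_nonzero:
            break
        zw = S.T @ f
        nw2 = float(zw @ zw)
        if nw2 <= opts.tol:
            break
        w = zw / np.sqrt(nw2)
        t = S @ w
        tt = float(t @ t)
        if tt <= opts.tol:
            break
        p_r = E.T @ t / tt
        q_r = float(f @ t) / tt
        f_prev = f
        E = E - np.outer(t, p_r)
        f = f - t * q_r
        target = y0 if opts.cov_target == "y" else f_prev - f_prev.mean()
        cov_r = float((target - target.mean()) @ (t - t.mean())) / (n - 1)
        for c in range(c_count):
            U_cols[c].append(u_this[c])
        W_cols.append(w)
        P_cols.append(p_r)
        q_vals.append(q_r)
        T_cols.append(t)
        cov_vals.append(cov_r)

    r_eff = len(W_cols)
    U = [
        np.column_stack(U_cols[c]) if r_eff else np.zeros((blocks[c].size, 0))
        for c in range(c_count)
    ]
    return MbplsModel(
        partition=partition,
        U=U,
        W=np.column_stack(W_cols) if r_eff else np.zeros((c_count, 0)),
        P=np.column_stack(P_cols) if r_eff else np.zeros((p, 0)),
        q=np.array(q_vals),
        T=np.column_stack(T_cols) if r_eff else np.zeros((n, 0)),
        cov_yt=np.array(cov_vals),
        variable_ids=list(ds.variable_ids),
        n_components_requested=opts.n_components,
        block_size_normalization=opts.block_size_normalization,
        scaling=scaling,
        response_name=ds.response_name,
    )


def _check_variables(model: MbplsModel, ds: Dataset) -> None:
    if list(ds.variable_ids) == list(model.variable_ids):
        return
    missing = sorted(set(model.variable_ids) - set(ds.variable_ids))
    extra = sorted(set(ds.variable_ids) - set(model.variable_ids))
    raise ValueError(
        "variable mismatch between model and new data; "
        f"missing={missing[:10]}, extra={extra[:10]} "
        "(ids must match the training order)"
    )


def _scaled_predictors(model: MbplsModel, ds: Dataset) -> np.ndarray:
    _check_variables(model, ds)
    if model.scaling is not None:
        return apply_scaling(ds, model.scaling).X
    return ds.X


def predict_components(model: MbplsModel, ds: Dataset) -> np.ndarray:
    """Cumulative predictions (original units) using the first r components.

    Returns an (n_new, R+1) matrix whose column r is the prediction with r
    components; column 0 is the intercept-only (training-mean) prediction.
    """
    E = _scaled_predictors(model, ds).copy()
    n = E.shape[0]
    blocks = model.partition.blocks()
    sizes = model.block_sizes.astype(float)
    out = np.zeros((n, model.n_components + 1))
    yhat = np.zeros(n)
    for r in range(model.n_components):
        S = np.zeros((n, model.n_blocks))
        for c, idx in enumerate(blocks):
            s = E[:, idx] @ model.U[c][:, r]
            S[:, c] = s / sizes[c] if model.block_size_normalization else s
        t = S @ model.W[:, r]
        E = E - np.outer(t, model.P[:, r])
        yhat = yhat + t * model.q[r]
        out[:, r + 1] = yhat
    if model.scaling is not None:
        out = invert_scaling(out, model.scaling, which="y")
    return out


def predict(model: MbplsModel, ds: Dataset) -> np.ndarray:
    """Predict the response for new data, in original response units.

    New data must carry exactly the training variables (checked by id); the
    stored training scaling is applied, the component loop is run with the
    same block-size normalization used in training, and the accumulated
    prediction is mapped back to original units.  A degenerate model with
    zero effective components predicts the training response mean.
    """
    return predict_components(model, ds)[:, -1]


def fitted_coefficients(model: MbplsModel) -> np.ndarray:
    """Implied length-p regression vector b in scaled space: yhat_scaled = X_scaled b.

    Built from the composite weight matrix A (per component, block segment
    w_r(c) u_r(c) / l(c)) via the standard PLS closed form
    b = A (P' A)^{-1} q.  Zero for a degenerate model.
    """
    r_eff = model.n_components
    if r_eff == 0:
        return np.zeros(model.p)
    blocks = model.partition.blocks()
    sizes = model.block_sizes.astype(float)
    A = np.zeros((model.p, r_eff))
    for c, idx in enumerate(blocks):
        scale = sizes[c] if model.block_size_normalization else 1.0
        A[idx, :] = model.U[c] * (model.W[c, :] / scale)
    return A @ np.linalg.solve(model.P.T @ A, model.q)
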