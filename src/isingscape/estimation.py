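"""Estimating Ising networks from binary data (nodewise logistic regression).

Each node is regressed on all other nodes with a logistic model; the
intercept of regression ``i`` is the threshold ``m_i`` and the averaged
cross-coefficients give the symmetric weight matrix (pseudo-likelihood
estimation).  The solver is a small Newton–Raphson (IRLS) routine with
an optional L2 ridge; it is exercised against scikit-learn's logistic
regression in the test suite and exists because bootstrap and
calibration workflows need many thousands of tiny refits.

Also provides the ordinal-to-binary recode (presence = value >= t) and
a scikit-learn-compatible estimator wrapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .core import IsingNetwork

__all__ = [
    "BinaryDataset",
    "EstimationError",
    "IsingEstimator",
    "binarize",
    "estimate_ising",
]

#: Thresholds of constant (all-0 or all-1) columns are clamped to
#: +/- DEGENERATE_CLAMP / beta so that landscapes remain finite.
DEGENERATE_CLAMP = 10.0

#: Coefficient magnitude beyond which an unpenalized fit is treated as
#: perfectly separated.
_SEPARATION_BOUND = 30.0


class EstimationError(RuntimeError):
    """Nodewise logistic regression failed (typically perfect separation)."""


@dataclass(frozen=True)
class BinaryDataset:
    """A persons x nodes matrix with entries in {0, 1}.

    ``values`` has one row per person and one column per node; node
    labels are unique.  Zero-row datasets are permitted (an empty
    dataset still has a valid header), but estimation requires at
    least two distinct rows.
    """

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"values must be 2-D (persons x nodes), got {v.ndim}-D")
        labels = tuple(str(x) for x in self.labels)
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        if v.shape[1] != len(labels):
            raise ValueError(
                f"{v.shape[1]} columns but {len(labels)} labels"
            )
        if v.size and not np.all((v == 0) | (v == 1)):
            raise ValueError("dataset entries must be exactly 0 or 1")
        v = v.astype(np.int8)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", labels)

    @property
    def person_count(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def symptom_counts(self) -> np.ndarray:
        """Row sums: number of active nodes per person."""
        return self.values.sum(axis=1)


def binarize(
    values,
    threshold: float = 1.0,
    labels: Sequence[str] | None = None,
) -> BinaryDataset:
    """Recode an ordinal persons x nodes matrix into presence/absence.

    An entry becomes 1 when it is ``>= threshold``; the default
    ``threshold = 1`` codes symptom absence (0) against any symptom
    presence.  Columns whose recoded values are constant are flagged
    with a warning — they are degenerate for estimation.
    """
    import pandas as pd

    if isinstance(values, pd.DataFrame):
        if labels is None:
            labels = [str(c) for c in values.columns]
        values = values.to_numpy()
    v = np.asarray(values)
    if v.ndim != 2:
        raise ValueError("values must be 2-D (persons x nodes)")
    if not np.issubdtype(v.dtype, np.number):
        raise ValueError("values must be numeric to binarize")
    if not np.all(np.isfinite(v.astype(float))):
        raise ValueError("values must be finite to binarize")
    if labels is None:
        labels = [f"x{i}" for i in range(v.shape[1])]
    out = (v >= threshold).astype(np.int8)
    if out.shape[0] > 0:
        constant = [
            str(labels[j])
            for j in range(out.shape[1])
            if np.all(out[:, j] == out[0, j])
        ]
        if constant:
            warnings.warn(
                "binarized columns are constant (degenerate for estimation): "
                + ", ".join(constant),
                UserWarning,
                stacklevel=2,
            )
    return BinaryDataset(values=out, labels=tuple(str(x) for x in labels))


def _logistic_newton(
    y: np.ndarray,
    x: np.ndarray,
    ridge: float,
    sample_weight: np.ndarray | None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> np.ndarray:
    """Fit logistic(y ~ 1 + x) by Newton-Raphson; returns [intercept, coefs].

    The ridge penalty (if any) applies to the slope coefficients only.
    Raises :class:`EstimationError` when an unpenalized fit diverges,
    which signals perfect separation.
    """
    n, p = x.shape
    design = np.empty((n, p + 1))
    design[:, 0] = 1.0
    design[:, 1:] = x
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    pen = np.full(p + 1, float(ridge))
    pen[0] = 0.0
    beta = np.zeros(p + 1)
    ybar = float(np.average(y, weights=w))
    ybar = min(max(ybar, 1e-9), 1 - 1e-9)
    beta[0] = np.log(ybar / (1 - ybar))
    for _ in range(max_iter):
        mu = expit(design @ beta)
        grad = design.T @ (w * (y - mu)) - pen * beta
        s = w * mu * (1.0 - mu)
        hess = (design * s[:, None]).T @ design
        hess[np.diag_indices_from(hess)] += pen + 1e-12
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - singular Hessian
            raise EstimationError(
                "logistic regression Hessian is singular; supply ridge > 0"
            ) from exc
        beta += step
        if ridge == 0.0 and np.max(np.abs(beta)) > _SEPARATION_BOUND:
            raise EstimationError(
                "perfect separation in nodewise logistic regression; "
                "supply a nonzero ridge penalty (e.g. ridge=1e-4)"
            )
        if np.max(np.abs(step)) < tol:
            return beta
    if ridge == 0.0:
        raise EstimationError(
            "nodewise logistic regression did not converge; "
            "supply a nonzero ridge penalty (e.g. ridge=1e-4)"
        )
    warnings.warn(
        "penalized logistic regression stopped before full convergence",
        UserWarning,
        stacklevel=2,
    )
    return beta


def _batched_nodewise_newton(
    v: np.ndarray,
    ridge: float,
    sample_weight: np.ndarray | None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """All N nodewise logistic regressions in one batched Newton loop.

    Equivalent to calling :func:`_logistic_newton` per node (same
    likelihood, same penalty), but iterating jointly over a stacked
    (N, persons, N) design tensor; bootstrap and calibration loops
    re-fit thousands of small networks and this removes the per-node
    Python overhead.  Returns ``(thresholds, coefficient_matrix)``.
    """
    n, n_nodes = v.shape
    full = np.empty((n, n_nodes + 1))
    full[:, 0] = 1.0
    full[:, 1:] = v
    # column indices per node: intercept then every other node
    idx = np.empty((n_nodes, n_nodes), dtype=np.intp)
    for i in range(n_nodes):
        idx[i, 0] = 0
        idx[i, 1:] = [j + 1 for j in range(n_nodes) if j != i]
    design = full[:, idx].transpose(1, 0, 2)  # (node, person, predictor)
    y = v.T  # (node, person)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    pen = np.full(n_nodes, float(ridge))
    diag = np.arange(n_nodes)
    beta = np.zeros((n_nodes, n_nodes))
    ybar = np.clip(np.average(y, axis=1, weights=w), 1e-9, 1 - 1e-9)
    beta[:, 0] = np.log(ybar / (1 - ybar))
    for _ in range(max_iter):
        mu = expit(np.einsum("inp,ip->in", design, beta))
        grad = np.einsum("inp,in->ip", design, w * (y - mu))
        grad[:, 1:] -= pen[None, 1:] * beta[:, 1:]
        s = w * mu * (1.0 - mu)
        hess = np.einsum("inp,in,inq->ipq", design, s, design)
        hess[:, diag, diag] += np.concatenate(([1e-12], pen[1:] + 1e-12))
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise EstimationError(
                "logistic regression Hessian is singular; supply ridge > 0"
            ) from exc
        beta += step
        if ridge == 0.0 and np.max(np.abs(beta)) > _SEPARATION_BOUND:
            raise EstimationError(
                "perfect separation in nodewise logistic regression; "
                "supply a nonzero ridge penalty (e.g. ridge=1e-4)"
            )
        if np.max(np.abs(step)) < tol:
            break
    else:
        if ridge == 0.0:
            raise EstimationError(
                "nodewise logistic regression did not converge; "
                "supply a nonzero ridge penalty (e.g. ridge=1e-4)"
            )
        warnings.warn(
            "penalized logistic regression stopped before full convergence",
            UserWarning,
            stacklevel=3,
        )
    thresholds = beta[:, 0].copy()
    coef = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        others = [j for j in range(n_nodes) if j != i]
        coef[i, others] = beta[i, 1:]
    return thresholds, coef


def estimate_ising(
    data: BinaryDataset,
    ridge: float = 0.0,
    *,
    beta: float = 1.0,
    sample_weight: np.ndarray | None = None,
    return_info: bool = False,
):
    """Estimate an Ising network by nodewise logistic regression.

    For each node ``i`` a logistic regression of ``a_i`` on all other
    nodes yields the threshold ``m_i`` (the intercept) and coefficients
    for every neighbour; the weight ``w_ij`` is the average of the two
    cross-coefficients from regressions ``i`` and ``j``
    (symmetrization by averaging).  ``beta`` is fixed at 1 by default,
    the scale on which logistic coefficients are identified.

    Constant columns cannot be regressed: their thresholds are clamped
    to ``+/- 10 / beta`` (sign matching the constant value), their
    weight row is zeroed, and a warning is emitted.  Unpenalized fits
    that hit perfect separation raise :class:`EstimationError`
    instructing a nonzero ``ridge``.

    With ``return_info=True`` also returns a metadata dict recording
    the ridge, the symmetrization rule, and any clamped columns.
    """
    if data.person_count < 2:
        raise ValueError("estimation requires at least 2 rows")
    v = data.values.astype(np.float64)
    n_nodes = data.n_nodes
    constant = [j for j in range(n_nodes) if np.all(v[:, j] == v[0, j])]
    if len(constant) == n_nodes:
        raise ValueError("estimation requires at least 2 distinct rows")
    free = [j for j in range(n_nodes) if j not in constant]
    if not constant:
        m, coef = _batched_nodewise_newton(v, float(ridge), sample_weight)
    else:
        m = np.zeros(n_nodes)
        coef = np.zeros((n_nodes, n_nodes))
        for i in free:
            others = [j for j in free if j != i]
            fit = _logistic_newton(
                v[:, i], v[:, others], float(ridge), sample_weight
            )
            m[i] = fit[0]
            coef[i, others] = fit[1:]
    w = (coef + coef.T) / 2.0
    np.fill_diagonal(w, 0.0)
    for j in constant:
        m[j] = (DEGENERATE_CLAMP if v[0, j] == 1 else -DEGENERATE_CLAMP) / beta
        w[j, :] = 0.0
        w[:, j] = 0.0
    if constant:
        warnings.warn(
            "constant columns clamped (threshold set to +/-"
            f"{DEGENERATE_CLAMP}/beta, weights zeroed): "
            + ", ".join(data.labels[j] for j in constant),
            UserWarning,
            stacklevel=2,
        )
    network = IsingNetwork(
        labels=data.labels, thresholds=m, weights=w, beta=beta
    )
    if return_info:
        info = {
            "method": "nodewise logistic regression (pseudo-likelihood)",
            "ridge": float(ridge),
            "symmetrization": "average",
            "clamped_columns": [data.labels[j] for j in constant],
            "n_persons": data.person_count,
            "weighted": sample_weight is not None,
        }
        return network, info
    return network


class IsingEstimator(BaseEstimator):
    """Scikit-learn-compatible wrapper around :func:`estimate_ising`.

    Parameters
    ----------
    ridge : float, default 0.0
        L2 penalty on the nodewise logistic slopes.
    beta : float, default 1.0
        Inverse temperature stored on the fitted network.
    binarize_threshold : float or None, default None
        If set, ordinal input is recoded to ``value >= threshold``
        before fitting.

    Attributes
    ----------
    network_ : IsingNetwork
        The fitted network.
    thresholds_, weights_ : ndarray
        Fitted parameter views of ``network_``.
    estimation_info_ : dict
        Estimation metadata (ridge, symmetrization rule, clamps).
    """

    def __init__(
        self,
        ridge: float = 0.0,
        beta: float = 1.0,
        binarize_threshold: float | None = None,
    ):
        self.ridge = ridge
        self.beta = beta
        self.binarize_threshold = binarize_threshold

    def fit(self, X, y=None):
        import pandas as pd

        labels = None
        if isinstance(X, pd.DataFrame):
            labels = [str(c) for c in X.columns]
        elif isinstance(X, BinaryDataset):
            labels = list(X.labels)
            X = X.values
        arr = np.asarray(X)
        if arr.ndim != 2:
            raise ValueError("X must be 2-D (persons x nodes)")
        if labels is None:
            labels = [f"x{i}" for i in range(arr.shape[1])]
        if self.binarize_threshold is not None:
            data = binarize(arr, threshold=self.binarize_threshold, labels=labels)
        else:
            data = BinaryDataset(values=arr, labels=tuple(labels))
        self.network_, self.estimation_info_ = estimate_ising(
            data, ridge=self.ridge, beta=self.beta, return_info=True
        )
        self.labels_ = self.network_.labels
        self.thresholds_ = self.network_.thresholds
        self.weights_ = self.network_.weights
        self.n_features_in_ = arr.shape[1]
        return self

    def stability_landscape(self):
        """Landscape of the fitted network."""
        from .landscape import potential_landscape

        check_is_fitted(self, "network_")
        return potential_landscape(self.network_)

    def stability_metrics(self, cutoff: int):
        """Phase-stability metrics of the fitted network at a cutoff."""
        from .metrics import phase_stability

        return phase_stability(self.stability_landscape(), cutoff)
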