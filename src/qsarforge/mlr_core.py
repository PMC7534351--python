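"""Ordinary-least-squares QSAR fitting, diagnostics, and leave-one-out validation.

Small-n QSAR practice reports a fixed set of statistics for a fitted
multiple linear regression: the squared correlation coefficient R², the
standard error of estimate s = sqrt(RSS/(n−p−1)), Fisher's F, and the
leave-one-out cross-validated Q² = 1 − PRESS/TSS. This module computes all
of them from first principles on raw (unstandardised) descriptor scales,
with the intercept always included.

The least-squares solve uses a pivoted orthogonal decomposition rather
than an explicit normal-equations inverse; rank deficiency is diagnosed
and reported by column name. Leave-one-out predictions use the hat-matrix
identity e_i / (1 − h_ii), which is algebraically exact for OLS and is
cross-checked against an explicit refit loop in the test suite.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy import stats as sps

from .dataset_io import QsarDataset, DatasetError

#: Relative condition threshold below which a design column is declared
#: linearly dependent on the others.
RANK_RTOL = 1e-10


class RankDeficiencyError(np.linalg.LinAlgError):
    """Collinear descriptor columns make the OLS solution non-unique."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


@dataclass(frozen=True)
class MLRModel:
    """A fitted linear model: pIC50 = intercept + sum(coefficients * descriptors)."""

    descriptor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    n: int

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.descriptor_names):
            raise DatasetError("one coefficient per descriptor required")
        if self.n < self.p + 2:
            raise DatasetError(f"n={self.n} too small for p={self.p} descriptors (need n >= p + 2)")

    @property
    def p(self) -> int:
        return len(self.descriptor_names)

    def equation(self, response: str = "pIC50", digits: int = 3) -> str:
        """Human-readable regression equation."""
        terms = [f"{c:+.{digits}f}*{nm}" for c, nm in zip(self.coefficients, self.descriptor_names)]
        return f"{response} = " + " ".join(terms) + f" {self.intercept:+.{digits}f}"


@dataclass(frozen=True)
class FitStats:
    """Training-set goodness-of-fit diagnostics of an intercept-containing OLS fit."""

    RSS: float
    TSS: float
    R2: float
    s: float        # sqrt(RSS / (n - p - 1)), the standard error of estimate
    F: float        # (R2/p) / ((1 - R2)/(n - p - 1))
    RMSE_train: float


@dataclass(frozen=True)
class LOOSummary:
    """Leave-one-out results: held-out predictions, PRESS, and Q² = 1 − PRESS/TSS."""

    heldout_predictions: tuple[float, ...]
    PRESS: float
    Q2: float


def design_matrix(X: np.ndarray) -> np.ndarray:
    """Prepend the intercept column of ones."""
    X = np.asarray(X, dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def _check_rank(A: np.ndarray, names: Sequence[str]) -> None:
    # Pivoted QR: columns pivoted beyond the numerical rank are the dependent ones.
    _, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > RANK_RTOL * diag.max()).sum()) if diag.size else 0
    if rank < A.shape[1]:
        labels = ["intercept"] + list(names)
        raise RankDeficiencyError([labels[j] for j in sorted(piv[rank:])])


def fit_ols(dataset: QsarDataset) -> MLRModel:
    """Fit ordinary least squares of the response on all dataset descriptors.

    Requires n >= p + 2 and a full-rank design (intercept plus descriptor
    columns). Deterministic: the unique RSS-minimising coefficient vector.
    """
    if dataset.n < dataset.p + 2:
        raise DatasetError(
            f"n={dataset.n} too small for p={dataset.p} descriptors (need n >= p + 2)")
    A = design_matrix(dataset.X)
    _check_rank(A, dataset.descriptor_names)
    beta, *_ = np.linalg.lstsq(A, dataset.y, rcond=None)
    return MLRModel(
        descriptor_names=tuple(dataset.descriptor_names),
        coefficients=tuple(float(b) for b in beta[1:]),
        intercept=float(beta[0]),
        n=dataset.n,
    )


def predict(model: MLRModel, rows: "np.ndarray | Sequence[Sequence[float]] | dict") -> np.ndarray:
    """Apply the linear form intercept + X @ coefficients to descriptor rows.

    ``rows`` may be an (m x p) array ordered like ``model.descriptor_names``,
    or a mapping / DataFrame-like with the model's descriptors as keys.
    """
    if hasattr(rows, "keys"):
        missing = [nm for nm in model.descriptor_names if nm not in rows.keys()]
        if missing:
            raise DatasetError(f"missing descriptors in prediction input: {missing}")
        X = np.column_stack([np.asarray(rows[nm], dtype=float) for nm in model.descriptor_names])
    else:
        X = np.atleast_2d(np.asarray(rows, dtype=float))
    if X.shape[1] != model.p:
        raise DatasetError(f"expected {model.p} descriptor columns, got {X.shape[1]}")
    return model.intercept + X @ np.asarray(model.coefficients)


def goodness_of_fit(model: MLRModel, dataset: QsarDataset) -> FitStats:
    """Training-set RSS, TSS, R², s, F and RMSE for a fitted model."""
    if tuple(dataset.descriptor_names) != model.descriptor_names:
        raise DatasetError(
            f"dataset descriptors {dataset.descriptor_names} do not match model "
            f"{list(model.descriptor_names)}")
    n, p = dataset.n, model.p
    if n <= p + 1:
        raise DatasetError(f"s undefined for n={n}, p={p} (need n > p + 1)")
    resid = dataset.y - predict(model, dataset.X)
    RSS = float(resid @ resid)
    TSS = float(((dataset.y - dataset.y.mean()) ** 2).sum())
    R2 = 1.0 - RSS / TSS
    dof = n - p - 1
    s = float(np.sqrt(RSS / dof))
    F = float((R2 / p) / ((1.0 - R2) / dof)) if R2 < 1.0 else float("inf")
    return FitStats(RSS=RSS, TSS=TSS, R2=R2, s=s, F=F, RMSE_train=float(np.sqrt(RSS / n)))


def loo_cross_validate(
    dataset: QsarDataset,
    descriptors: Sequence[str] | None = None,
    method: str = "hat",
) -> LOOSummary:
    """Leave-one-out cross-validation of the OLS model on the given descriptors.

    Each compound is predicted by a model fitted on the other n−1; PRESS is
    the sum of squared held-out errors and Q² = 1 − PRESS/TSS, with TSS
    taken about the mean of the full training response (the usual QSAR
    convention). ``method='hat'`` uses the exact closed form
    e_i/(1 − h_ii); ``method='refit'`` runs the explicit n-fold loop.
    """
    ds = dataset.subset(descriptors) if descriptors is not None else dataset
    n, p = ds.n, ds.p
    if n < p + 3:
        raise DatasetError(f"leave-one-out needs n >= p + 3 (got n={n}, p={p})")
    A = design_matrix(ds.X)
    _check_rank(A, ds.descriptor_names)

    if method == "hat":
        beta, *_ = np.linalg.lstsq(A, ds.y, rcond=None)
        resid = ds.y - A @ beta
        Q, _ = np.linalg.qr(A)
        h = np.einsum("ij,ij->i", Q, Q)
        if np.any(h >= 1.0 - 1e-12):
            raise DatasetError("leverage ~1: a fold's held-out point is not predictable")
        heldout_err = resid / (1.0 - h)
        preds = ds.y - heldout_err
    elif method == "refit":
        preds = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            Ai = A[keep]
            _check_rank(Ai, ds.descriptor_names)
            beta_i, *_ = np.linalg.lstsq(Ai, ds.y[keep], rcond=None)
            preds[i] = A[i] @ beta_i
        heldout_err = ds.y - preds
    else:
        raise ValueError(f"unknown LOO method {method!r}")

    PRESS = float(heldout_err @ heldout_err)
    TSS = float(((ds.y - ds.y.mean()) ** 2).sum())
    return LOOSummary(
        heldout_predictions=tuple(float(v) for v in preds),
        PRESS=PRESS,
        Q2=1.0 - PRESS / TSS,
    )


def prediction_band(
    model: MLRModel,
    dataset: QsarDataset,
    level: float = 0.95,
    rows: np.ndarray | None = None,
) -> dict:
    """Classical OLS confidence and prediction half-widths at each point.

    For a point x with hat value h = x'(X'X)^{-1}x, the mean-response
    confidence half-width is t * s * sqrt(h) and the new-observation
    prediction half-width is t * s * sqrt(1 + h), with t the two-sided
    quantile of Student's t on n − p − 1 degrees of freedom. The prediction
    half-width therefore strictly exceeds the confidence half-width
    wherever s > 0.

    Returns a dict with ``fit``, ``confidence_halfwidth``,
    ``prediction_halfwidth`` and ``zero_width_warning`` (True when s = 0).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"coverage level must be in (0, 1), got {level}")
    stats_ = goodness_of_fit(model, dataset)
    A = design_matrix(dataset.X)
    Xq = design_matrix(rows) if rows is not None else A
    XtX_inv = np.linalg.inv(A.T @ A)
    h = np.einsum("ij,jk,ik->i", Xq, XtX_inv, Xq)
    t = float(sps.t.ppf(0.5 + level / 2.0, dataset.n - model.p - 1))
    # perfect interpolation leaves RSS at rounding-noise level, not exact zero
    zero = stats_.s <= 1e-12 * max(1.0, float(np.abs(dataset.y).max()))
    if zero:
        warnings.warn("residual scale s = 0: bands have zero width", stacklevel=2)
    conf = t * stats_.s * np.sqrt(h)
    pred = t * stats_.s * np.sqrt(1.0 + h)
    return {
        "fit": predict(model, Xq[:, 1:]),
        "confidence_halfwidth": conf,
        "prediction_halfwidth": pred,
        "level": level,
        "zero_width_warning": bool(zero),
    }


# ---------------------------------------------------------------------------
# Model artifact serialisation
# ---------------------------------------------------------------------------

def _dataset_fingerprint(dataset: QsarDataset) -> str:
    hasher = hashlib.sha256()
    hasher.update(",".join(dataset.ids).encode())
    hasher.update(",".join(dataset.descriptor_names).encode())
    hasher.update(np.ascontiguousarray(dataset.X).tobytes())
    hasher.update(np.ascontiguousarray(dataset.y).tobytes())
    return hasher.hexdigest()[:16]


def model_to_json(
    model: MLRModel,
    dataset: QsarDataset,
    stats: FitStats | None = None,
    loo: LOOSummary | None = None,
    path: str | Path | None = None,
) -> dict:
    """Serialise a fitted model with its diagnostics and a training-data hash."""
    payload = {
        "descriptor_names": list(model.descriptor_names),
        "coefficients": list(model.coefficients),
        "intercept": model.intercept,
        "n": model.n,
        "p": model.p,
        "equation": model.equation(),
        "fit_stats": asdict(stats) if stats else None,
        "loo": {"PRESS": loo.PRESS, "Q2": loo.Q2,
                "heldout_predictions": list(loo.heldout_predictions)} if loo else None,
        "training_data_fingerprint": _dataset_fingerprint(dataset),
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=1))
    return payload
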