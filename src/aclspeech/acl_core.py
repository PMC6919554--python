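"""Articulation-constrained learning (ACL): objective and solvers.

ACL fits a sparse linear emotion classifier whose weight vector is jointly
optimized to (i) separate binary emotion labels from supra-segmental acoustic
features via cross-entropy and (ii) reconstruct per-segment articulatory
kinematic targets (e.g. mean jaw height) by linear regression from the same
feature space.  For a single target the objective is

    f(w) = -1/N sum_i [ y_i log s(w.x_i) + (1-y_i) log(1 - s(w.x_i)) ]
           + lambda1 * ||w||_1
           + lambda2/M * sum_j (a_j - w.x_j)^2

with s the logistic function.  lambda1 controls sparsity, lambda2 the weight
of articulatory reconstruction relative to classification.  The classification
rows (x_i, y_i) and reconstruction rows (x_j, a_j) may come from different
speakers or different corpora; only acoustic features are needed at inference
time.  With K targets, one weight column is fit independently per target and
the columns are stacked into W = [w_1, ..., w_K].

The reference solver is accelerated proximal gradient (FISTA) with
soft-thresholding, which produces exact zeros on inactive coordinates.  The
objective is convex, so the attained objective value is solver-independent
within the convergence tolerance.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ClassificationSet",
    "ReconstructionSet",
    "RegularizationConfig",
    "FitDiagnostics",
    "ACLModel",
    "ConvergenceError",
    "sigmoid",
    "cross_entropy",
    "l1_objective",
    "acl_objective",
    "smooth_gradient",
    "fit_single_target",
    "fit_multi_target",
    "fit_l1_logistic",
    "fit_articulation_only",
    "fit_ar_model",
    "standardize_columns",
]

DEFAULT_TOLERANCE = 1e-5
DEFAULT_MAX_ITER = 10_000

MODEL_FORMAT_VERSION = 1


class ConvergenceError(RuntimeError):
    """Solver failed to reach the requested tolerance within max_iter."""

    def __init__(self, message: str, diagnostics: "FitDiagnostics | None" = None):
        super().__init__(message)
        self.diagnostics = diagnostics


# ---------------------------------------------------------------------------
# Sample sets
# ---------------------------------------------------------------------------


@dataclass
class ClassificationSet:
    """Acoustic features with binary emotion labels (the N classification rows)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d array")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} labels"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite entries in X")
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("y must be binary (0/1)")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def require_both_classes(self) -> None:
        if self.n_samples < 2 or len(np.unique(self.y)) < 2:
            raise ValueError("classification set must contain both classes")


@dataclass
class ReconstructionSet:
    """Acoustic features paired with K articulatory targets (the M rows).

    May come from a different corpus / different speakers than the
    classification set; only the feature space must match.
    """

    Xr: np.ndarray
    A: np.ndarray
    target_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.Xr = np.asarray(self.Xr, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim == 1:
            self.A = self.A[:, None]
        if self.Xr.ndim != 2 or self.A.ndim != 2:
            raise ValueError("Xr and A must be 2-d arrays")
        if self.Xr.shape[0] != self.A.shape[0]:
            raise ValueError("Xr and A must have the same number of rows")
        if not np.all(np.isfinite(self.Xr)) or not np.all(np.isfinite(self.A)):
            raise ValueError("non-finite entries in reconstruction set")
        if not self.target_names:
            self.target_names = tuple(f"TARGET_{k}" for k in range(self.A.shape[1]))
        if len(self.target_names) != self.A.shape[1]:
            raise ValueError("target_names length must equal number of target columns")

    @property
    def n_samples(self) -> int:
        return self.Xr.shape[0]

    @property
    def n_features(self) -> int:
        return self.Xr.shape[1]

    @property
    def n_targets(self) -> int:
        return self.A.shape[1]

    def column(self, k: int) -> "ReconstructionSet":
        return ReconstructionSet(self.Xr, self.A[:, [k]], (self.target_names[k],))


@dataclass
class RegularizationConfig:
    """Per-target (lambda1, lambda2) pairs.

    Scalars broadcast over all K targets.  lambda1 > 0 controls sparsity,
    lambda2 >= 0 the weight of articulatory reconstruction.
    """

    lambda1: np.ndarray
    lambda2: np.ndarray

    def __init__(self, lambda1, lambda2) -> None:
        self.lambda1 = np.atleast_1d(np.asarray(lambda1, dtype=float))
        self.lambda2 = np.atleast_1d(np.asarray(lambda2, dtype=float))
        if np.any(self.lambda1 <= 0):
            raise ValueError("lambda1 must be positive")
        if np.any(self.lambda2 < 0):
            raise ValueError("lambda2 must be nonnegative")

    def per_target(self, n_targets: int) -> tuple[np.ndarray, np.ndarray]:
        l1 = np.broadcast_to(self.lambda1, (n_targets,)).copy() if self.lambda1.size in (1, n_targets) else None
        l2 = np.broadcast_to(self.lambda2, (n_targets,)).copy() if self.lambda2.size in (1, n_targets) else None
        if l1 is None or l2 is None:
            raise ValueError("lambda arrays must be scalar or length K")
        return l1, l2


@dataclass
class FitDiagnostics:
    """Bookkeeping from one single-target fit."""

    objective: float
    n_iter: int
    requested_tolerance: float
    achieved_tolerance: float
    subgradient_residual: float
    n_zero: int
    converged: bool


# ---------------------------------------------------------------------------
# Objective pieces
# ---------------------------------------------------------------------------


def sigmoid(z):
    """Numerically stable logistic function 1 / (1 + exp(-z))."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if out.ndim == 0:
        return float(out)
    return out


def _log_loss_terms(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    # -[y log s(z) + (1-y) log(1-s(z))] = softplus(z) - y z, computed without
    # ever forming a saturated probability (equivalent to eps-clamping the log).
    return np.logaddexp(0.0, z) - y * z

def cross_entropy(w: np.ndarray, data: ClassificationSet) -> float:
    """Mean cross-entropy of the logistic model w over the classification set."""
    w = np.asarray(w, dtype=float).ravel()
    if w.shape[0] != data.n_features:
        raise ValueError(
            f"weight length {w.shape[0]} != feature dimension {data.n_features}"
        )
    z = data.X @ w
    return float(np.mean(_log_loss_terms(z, data.y)))


def l1_objective(w: np.ndarray, data: ClassificationSet, lambda1: float) -> float:
    """Cross-entropy plus L1 penalty (the sparse logistic-regression objective)."""
    if lambda1 < 0:
        raise ValueError("lambda1 must be nonnegative")
    w = np.asarray(w, dtype=float).ravel()
    return cross_entropy(w, data) + lambda1 * float(np.sum(np.abs(w)))


def acl_objective(
    w: np.ndarray,
    data: ClassificationSet,
    recon: ReconstructionSet | None,
    lambda1: float,
    lambda2: float,
) -> float:
    """Full single-target ACL objective: L1 logistic plus mean-squared
    articulatory reconstruction error weighted by lambda2."""
    w = np.asarray(w, dtype=float).ravel()
    value = l1_objective(w, data, lambda1)
    if lambda2 > 0:
        if recon is None or recon.n_samples == 0:
            raise ValueError("lambda2 > 0 requires a nonempty reconstruction set")
        if recon.n_targets != 1:
            raise ValueError("acl_objective expects a single-target reconstruction set")
        if recon.n_features != data.n_features:
            raise ValueError("feature dimension mismatch between data and recon")
        resid = recon.A[:, 0] - recon.Xr @ w
        value += lambda2 * float(np.mean(resid**2))
    return value


def smooth_gradient(
    w: np.ndarray,
    data: ClassificationSet,
    recon: ReconstructionSet | None,
    lambda2: float,
) -> np.ndarray:
    """Gradient of the smooth part (cross-entropy + reconstruction term)."""
    w = np.asarray(w, dtype=float).ravel()
    z = data.X @ w
    grad = data.X.T @ (sigmoid(z) - data.y) / data.n_samples
    if lambda2 > 0:
        if recon is None or recon.n_samples == 0:
            raise ValueError("lambda2 > 0 requires a nonempty reconstruction set")
        resid = recon.Xr @ w - recon.A[:, 0]
        grad = grad + (2.0 * lambda2 / recon.n_samples) * (recon.Xr.T @ resid)
    return grad


def _soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _subgradient_residual(grad: np.ndarray, w: np.ndarray, lambda1: float) -> float:
    # Distance of 0 from the subdifferential of the full objective, inf-norm.
    active = w != 0
    res = np.where(
        active,
        np.abs(grad + lambda1 * np.sign(w)),
        np.maximum(np.abs(grad) - lambda1, 0.0),
    )
    return float(np.max(res)) if res.size else 0.0


def _lipschitz_bound(
    data: ClassificationSet, recon: ReconstructionSet | None, lambda2: float
) -> float:
    # Hessian of the smooth part <= X'X/(4N) + (2 lambda2 / M) Xr'Xr.
    L = np.linalg.norm(data.X, 2) ** 2 / (4.0 * data.n_samples)
    if lambda2 > 0 and recon is not None and recon.n_samples > 0:
        L += 2.0 * lambda2 * np.linalg.norm(recon.Xr, 2) ** 2 / recon.n_samples
    return max(L, 1e-12)


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------


def fit_single_target(
    data: ClassificationSet,
    recon: ReconstructionSet | None,
    lambda1: float,
    lambda2: float = 0.0,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, FitDiagnostics]:
    """Minimize the single-target ACL objective with FISTA.

    Deterministic (initialized at w = 0).  Convergence requires both a relative
    objective change <= tolerance and a subgradient-optimality residual
    <= 10 * tolerance; failure raises :class:`ConvergenceError` carrying the
    diagnostics accumulated so far.
    """
    data.require_both_classes()
    if lambda1 <= 0:
        raise ValueError("lambda1 must be positive")
    if lambda2 > 0 and (recon is None or recon.n_samples == 0):
        raise ValueError("lambda2 > 0 requires a nonempty reconstruction set")
    if recon is not None and recon.n_targets != 1:
        raise ValueError("fit_single_target expects a single-target reconstruction set")
    if recon is not None and recon.n_features != data.n_features:
        raise ValueError("feature dimension mismatch between data and recon")

    D = data.n_features
    L = _lipschitz_bound(data, recon, lambda2)
    w = np.zeros(D)
    v = w.copy()
    t = 1.0
    f_w = acl_objective(w, data, recon, lambda1, lambda2)
    rel_change = np.inf
    residual = np.inf

    for it in range(1, max_iter + 1):
        grad_v = smooth_gradient(v, data, recon, lambda2)
        w_new = _soft_threshold(v - grad_v / L, lambda1 / L)
        f_new = acl_objective(w_new, data, recon, lambda1, lambda2)
        if f_new > f_w:
            # adaptive restart: drop momentum, retake the step from w
            t = 1.0
            v = w.copy()
            grad_v = smooth_gradient(v, data, recon, lambda2)
            w_new = _soft_threshold(v - grad_v / L, lambda1 / L)
            f_new = acl_objective(w_new, data, recon, lambda1, lambda2)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        v = w_new + ((t - 1.0) / t_new) * (w_new - w)
        rel_change = abs(f_w - f_new) / max(1.0, abs(f_w))
        w, f_w, t = w_new, f_new, t_new
        if rel_change <= tolerance:
            grad_w = smooth_gradient(w, data, recon, lambda2)
            residual = _subgradient_residual(grad_w, w, lambda1)
            if residual <= 10.0 * tolerance:
                diag = FitDiagnostics(
                    objective=f_w,
                    n_iter=it,
                    requested_tolerance=tolerance,
                    achieved_tolerance=rel_change,
                    subgradient_residual=residual,
                    n_zero=int(np.sum(w == 0.0)),
                    converged=True,
                )
                return w, diag

    diag = FitDiagnostics(
        objective=f_w,
        n_iter=max_iter,
        requested_tolerance=tolerance,
        achieved_tolerance=rel_change,
        subgradient_residual=residual,
        n_zero=int(np.sum(w == 0.0)),
        converged=False,
    )
    raise ConvergenceError(
        f"FISTA did not converge in {max_iter} iterations "
        f"(rel change {rel_change:.2e}, subgradient residual {residual:.2e})",
        diag,
    )


def fit_articulation_only(recon: ReconstructionSet, k: int = 0) -> np.ndarray:
    """Least-squares regression of one articulatory target on the acoustic
    features (the AR criterion); minimum-norm solution when rank-deficient."""
    if recon.n_samples < 1:
        raise ValueError("reconstruction set is empty")
    w, *_ = np.linalg.lstsq(recon.Xr, recon.A[:, k], rcond=None)
    return w


# ---------------------------------------------------------------------------
# Standardization and the fitted model
# ---------------------------------------------------------------------------


def standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column center/scale; zero-variance columns get scale 1."""
    X = np.asarray(X, dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - center) / scale, center, scale


@dataclass
class ACLModel:
    """A fitted articulation-constrained model.

    Holds the weight matrix W (one column per articulatory target, in
    standardized feature space), the target names and their anatomical groups,
    and the feature/target centering and scaling parameters so that inference
    on raw acoustic features is self-contained.
    """

    W: np.ndarray
    target_names: tuple[str, ...]
    target_groups: tuple[str, ...]
    feature_names: tuple[str, ...]
    feature_center: np.ndarray
    feature_scale: np.ndarray
    target_center: np.ndarray
    target_scale: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray
    diagnostics: tuple[FitDiagnostics, ...] = ()

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim == 1:
            self.W = self.W[:, None]
        if not np.all(np.isfinite(self.W)):
            raise ValueError("non-finite weights")
        self.feature_center = np.asarray(self.feature_center, dtype=float)
        self.feature_scale = np.asarray(self.feature_scale, dtype=float)
        self.target_center = np.atleast_1d(np.asarray(self.target_center, dtype=float))
        self.target_scale = np.atleast_1d(np.asarray(self.target_scale, dtype=float))
        self.lambda1 = np.atleast_1d(np.asarray(self.lambda1, dtype=float))
        self.lambda2 = np.atleast_1d(np.asarray(self.lambda2, dtype=float))
        self.target_names = tuple(self.target_names)
        self.target_groups = tuple(self.target_groups)
        self.feature_names = tuple(self.feature_names)

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    @property
    def n_targets(self) -> int:
        return self.W.shape[1]

    def scale_features(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        return (X - self.feature_center) / self.feature_scale

    def target_index(self, name: str) -> int:
        try:
            return self.target_names.index(name)
        except ValueError:
            raise KeyError(f"unknown target {name!r}") from None

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        def _decimals(values) -> list[str]:
            # repr of a Python float round-trips bit-faithfully
            return [repr(float(x)) for x in values]

        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "target_names": list(self.target_names),
            "target_groups": list(self.target_groups),
            "feature_names": list(self.feature_names),
            "W_columns": [_decimals(col) for col in self.W.T],
            "feature_center": _decimals(self.feature_center),
            "feature_scale": _decimals(self.feature_scale),
            "target_center": _decimals(self.target_center),
            "target_scale": _decimals(self.target_scale),
            "lambda1": _decimals(self.lambda1),
            "lambda2": _decimals(self.lambda2),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ACLModel":
        payload = json.loads(text)
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version: {version}")
        W = np.array([[float(x) for x in col] for col in payload["W_columns"]]).T
        return cls(
            W=W,
            target_names=tuple(payload["target_names"]),
            target_groups=tuple(payload["target_groups"]),
            feature_names=tuple(payload["feature_names"]),
            feature_center=np.array([float(x) for x in payload["feature_center"]]),
            feature_scale=np.array([float(x) for x in payload["feature_scale"]]),
            target_center=np.array([float(x) for x in payload["target_center"]]),
            target_scale=np.array([float(x) for x in payload["target_scale"]]),
            lambda1=np.array([float(x) for x in payload["lambda1"]]),
            lambda2=np.array([float(x) for x in payload["lambda2"]]),
        )

    def save(self, path) -> None:
        with io.open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "ACLModel":
        with io.open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def _infer_groups(target_names: Sequence[str]) -> tuple[str, ...]:
    # Anatomical group = leading name component ("JAW_POS_Y" -> "JAW").
    return tuple(name.split("_")[0] for name in target_names)


def fit_multi_target(
    data: ClassificationSet,
    recon: ReconstructionSet | None,
    config: RegularizationConfig,
    feature_names: Sequence[str] | None = None,
    target_groups: Sequence[str] | None = None,
    standardize: bool = True,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ACLModel:
    """Fit one weight column per articulatory target (independently, so the
    result does not depend on execution order) and stack them into an ACLModel.

    With ``recon=None`` (or all lambda2 = 0) this degenerates to plain
    L1-regularized logistic regression with a single "LOGIT" column — the
    acoustic-only (ACO) criterion.
    """
    D = data.n_features
    if feature_names is None:
        feature_names = tuple(f"F{i}" for i in range(D))
    if len(feature_names) != D:
        raise ValueError("feature_names length must equal feature dimension")

    if standardize:
        Xs, f_center, f_scale = standardize_columns(data.X)
    else:
        Xs, f_center, f_scale = data.X, np.zeros(D), np.ones(D)
    data_s = ClassificationSet(Xs, data.y)

    if recon is None:
        K = 1
        target_names: tuple[str, ...] = ("LOGIT",)
        t_center = np.zeros(1)
        t_scale = np.ones(1)
        recon_s = None
    else:
        if recon.n_features != D:
            raise ValueError("feature dimension mismatch between data and recon")
        K = recon.n_targets
        target_names = recon.target_names
        if standardize:
            Xr_s, _, _ = standardize_columns(recon.Xr)
            A_s, t_center, t_scale = standardize_columns(recon.A)
        else:
            Xr_s, A_s = recon.Xr, recon.A
            t_center, t_scale = np.zeros(K), np.ones(K)
        recon_s = ReconstructionSet(Xr_s, A_s, target_names)

    if target_groups is None:
        target_groups = _infer_groups(target_names)
    l1, l2 = config.per_target(K)

    columns = []
    diags = []
    for k in range(K):
        recon_k = recon_s.column(k) if recon_s is not None else None
        try:
            w_k, diag = fit_single_target(
                data_s, recon_k, l1[k], l2[k], tolerance=tolerance, max_iter=max_iter
            )
        except ConvergenceError as err:
            raise ConvergenceError(
                f"target {target_names[k]!r}: {err}", err.diagnostics
            ) from err
        columns.append(w_k)
        diags.append(diag)

    return ACLModel(
        W=np.column_stack(columns),
        target_names=target_names,
        target_groups=tuple(target_groups),
        feature_names=tuple(feature_names),
        feature_center=f_center,
        feature_scale=f_scale,
        target_center=t_center,
        target_scale=t_scale,
        lambda1=l1,
        lambda2=l2,
        diagnostics=tuple(diags),
    )


def fit_l1_logistic(
    data: ClassificationSet,
    lambda1: float,
    feature_names: Sequence[str] | None = None,
    standardize: bool = True,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ACLModel:
    """Acoustic-only (ACO) criterion: plain L1 logistic regression."""
    return fit_multi_target(
        data,
        recon=None,
        config=RegularizationConfig(lambda1, 0.0),
        feature_names=feature_names,
        standardize=standardize,
        tolerance=tolerance,
        max_iter=max_iter,
    )


def fit_ar_model(
    recon: ReconstructionSet,
    feature_names: Sequence[str] | None = None,
    target_groups: Sequence[str] | None = None,
    standardize: bool = True,
) -> ACLModel:
    """Articulation-only (AR) criterion: per-target least-squares regression."""
    D = recon.n_features
    if feature_names is None:
        feature_names = tuple(f"F{i}" for i in range(D))
    if standardize:
        Xr_s, f_center, f_scale = standardize_columns(recon.Xr)
        A_s, t_center, t_scale = standardize_columns(recon.A)
    else:
        Xr_s, A_s = recon.Xr, recon.A
        f_center, f_scale = np.zeros(D), np.ones(D)
        t_center, t_scale = np.zeros(recon.n_targets), np.ones(recon.n_targets)
    recon_s = ReconstructionSet(Xr_s, A_s, recon.target_names)
    W = np.column_stack(
        [fit_articulation_only(recon_s, k) for k in range(recon.n_targets)]
    )
    if target_groups is None:
        target_groups = _infer_groups(recon.target_names)
    return ACLModel(
        W=W,
        target_names=recon.target_names,
        target_groups=tuple(target_groups),
        feature_names=tuple(feature_names),
        feature_center=f_center,
        feature_scale=f_scale,
        target_center=t_center,
        target_scale=t_scale,
        lambda1=np.full(recon.n_targets, np.nan),
        lambda2=np.full(recon.n_targets, np.nan),
    )
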