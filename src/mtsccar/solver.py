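"""Alternating iteratively-reweighted solver for MT-SCCAR.

The model couples, per imaging modality m (a "task"), a sparse CCA between
genotypes X and imaging QTs Y_m with a linear regression of the imaging
projection Y_m v_m onto each cognitive score z_c:

    min_{U,V}  sum_m sum_c ||Y_m v_m - z_c||^2  +  sum_m ||X u_m - Y_m v_m||^2
               + lam_v1 ||V||_{2,1} + lam_v2 ||V||_{1,1}
               + lam_u1 ||U||_{2,1} + lam_u2 ||U||_{1,1} + lam_u3 ||U||_G
    s.t.       ||X u_m||^2 = 1,  ||Y_m v_m||^2 = 1  for every task m.

The non-smooth penalties are handled by iterative reweighting: each norm is
majorized by a quadratic with diagonal weight matrices D recomputed from the
previous iterate, so each half-step reduces to a symmetric positive-definite
linear solve followed by rescaling onto the unit-variance constraint.  The
constraints enter the half-step systems through multiplier terms
gamma_v ||Y_m v_m||^2 and gamma_u ||X u_m||^2 (gamma fixed to 1 by default).

Dropping the regression term (``regression_on=False``) recovers the plain
multi-task SCCA (MTSCCA) baseline; :func:`fit_mtscca` is that ablation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .datasets import GroupStructure, StudyDataset

__all__ = [
    "Hyperparameters",
    "CanonicalWeights",
    "FitResult",
    "reweighting_diagonals",
    "objective",
    "update_v",
    "update_u",
    "fit",
    "fit_mtscca",
    "NumericalError",
]

#: smoothing constant inside every reweighting denominator, guarding the
#: 1/(2||w||) weights against exactly-zero rows
DEFAULT_EPS = 1e-6


class NumericalError(RuntimeError):
    """Raised when a half-step linear system is singular or iterates diverge."""


@dataclass(frozen=True)
class Hyperparameters:
    """Regularization and constraint-multiplier parameters.

    The five ``lambda`` values weight the sparsity penalties (L2,1 and L1,1
    on both weight matrices, plus the SNP group penalty on U); they are the
    quantities tuned by cross-validation over {1e-3, ..., 1e3}.  ``gamma_u``
    and ``gamma_v`` multiply the constraint surrogates and mainly control
    the weight amplitude; they are fixed to 1.  ``regression_on=False``
    removes the cognitive-score regression, giving the MTSCCA ablation.

    The defaults are the values a nested five-fold grid search selects on
    the reference synthetic design at unit noise (see the methods notes);
    real studies should re-tune via :func:`mtsccar.nested_grid_search`.
    """

    lambda_u1: float = 0.1
    lambda_u2: float = 0.1
    lambda_u3: float = 0.0
    lambda_v1: float = 0.1
    lambda_v2: float = 0.1
    gamma_u: float = 1.0
    gamma_v: float = 1.0
    regression_on: bool = True

    def __post_init__(self) -> None:
        for name in ("lambda_u1", "lambda_u2", "lambda_u3", "lambda_v1", "lambda_v2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.gamma_u <= 0 or self.gamma_v <= 0:
            raise ValueError("gamma_u and gamma_v must be positive")

    def replace(self, **kwargs) -> "Hyperparameters":
        return dataclasses.replace(self, **kwargs)


@dataclass
class CanonicalWeights:
    """Canonical weight matrices, one column per modality task.

    ``U`` is p x M (SNP side), ``V`` is q x M (imaging QT side).  After a
    completed fit each column satisfies the unit-variance projection
    constraints ||X u_m||^2 = 1 and ||Y_m v_m||^2 = 1.
    """

    U: np.ndarray
    V: np.ndarray
    snp_ids: list | None = None
    qt_ids: list | None = None
    modality_names: list | None = None


@dataclass
class Diagonals:
    """Reweighting diagonal matrices, stored as their diagonals.

    Entry i of ``d_v1`` is 1 / (2 (||V_{i,:}||_2 + eps)); ``d_v2[:, m]``
    holds 1 / (2 (|v_{im}| + eps)); ``d_u1``/``d_u2`` are the analogues on
    U; ``d_u3`` is constant within each SNP group with value
    1 / (2 (||U_{g_k,:}||_F + eps)).
    """

    d_v1: np.ndarray | None = None
    d_v2: np.ndarray | None = None
    d_u1: np.ndarray | None = None
    d_u2: np.ndarray | None = None
    d_u3: np.ndarray | None = None


@dataclass
class FitResult:
    weights: CanonicalWeights
    converged: bool
    n_iterations: int
    objective_trace: np.ndarray
    per_task_training_ccc: np.ndarray
    max_constraint_violation: float
    final_delta_u: float
    final_delta_v: float
    hyper: Hyperparameters = field(default_factory=Hyperparameters)

    def diagnostics(self) -> dict:
        """JSON-serializable fit report."""
        return {
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "final_delta_u": float(self.final_delta_u),
            "final_delta_v": float(self.final_delta_v),
            "max_constraint_violation": float(self.max_constraint_violation),
            "per_task_training_ccc": [float(c) for c in self.per_task_training_ccc],
            "objective_final": float(self.objective_trace[-1]),
            "hyperparameters": dataclasses.asdict(self.hyper),
        }


def reweighting_diagonals(
    U: np.ndarray | None = None,
    V: np.ndarray | None = None,
    groups: GroupStructure | None = None,
    eps: float = DEFAULT_EPS,
) -> Diagonals:
    """Compute the smoothed reweighting diagonals from the current iterate."""
    out = Diagonals()
    if V is not None:
        V = np.atleast_2d(np.asarray(V, dtype=float))
        out.d_v1 = 1.0 / (2.0 * (np.linalg.norm(V, axis=1) + eps))
        out.d_v2 = 1.0 / (2.0 * (np.abs(V) + eps))
    if U is not None:
        U = np.atleast_2d(np.asarray(U, dtype=float))
        out.d_u1 = 1.0 / (2.0 * (np.linalg.norm(U, axis=1) + eps))
        out.d_u2 = 1.0 / (2.0 * (np.abs(U) + eps))
        if groups is not None:
            d3 = np.empty(U.shape[0])
            for idx in groups.indices().values():
                d3[idx] = 1.0 / (2.0 * (np.linalg.norm(U[idx, :]) + eps))
            out.d_u3 = d3
    return out


def objective(
    X: np.ndarray,
    Ys: list[np.ndarray],
    Z: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    hyper: Hyperparameters,
    groups: GroupStructure | None = None,
) -> float:
    """Value of the penalized objective (constraint multipliers excluded).

    The gamma terms are constraint surrogates, not part of the modeled
    loss, and are deliberately left out of the reported value.
    """
    from .penalties import penalty_group, penalty_l11, penalty_l21

    total = 0.0
    for m, Y in enumerate(Ys):
        proj = Y @ V[:, m]
        if hyper.regression_on:
            total += float(((proj[:, None] - Z) ** 2).sum())
        total += float(((X @ U[:, m] - proj) ** 2).sum())
    total += hyper.lambda_v1 * penalty_l21(V) + hyper.lambda_v2 * penalty_l11(V)
    total += hyper.lambda_u1 * penalty_l21(U) + hyper.lambda_u2 * penalty_l11(U)
    if hyper.lambda_u3 > 0:
        if groups is None:
            raise ValueError("lambda_u3 > 0 requires a SNP group structure")
        total += hyper.lambda_u3 * penalty_group(U, groups)
    return total


def _solve_spd(A: np.ndarray, b: np.ndarray, what: str) -> np.ndarray:
    try:
        x = scipy.linalg.solve(A, b, assume_a="pos")
    except (scipy.linalg.LinAlgError, ValueError) as err:
        raise NumericalError(
            f"singular system in the {what} half-step; consider a larger "
            "penalty weight or smoothing eps"
        ) from err
    if not np.all(np.isfinite(x)):
        raise NumericalError(f"non-finite solution in the {what} half-step")
    return x


def update_v(
    X: np.ndarray,
    Ys: list[np.ndarray],
    Z: np.ndarray,
    U: np.ndarray,
    V_prev: np.ndarray,
    hyper: Hyperparameters,
    eps: float = DEFAULT_EPS,
    return_prenorm: bool = False,
    regression_hessian: str = "printed",
    cov_mode: str = "identity",
    gram_Ys: list[np.ndarray] | None = None,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """One reweighted half-step on the imaging-side weights V.

    For each task the fixed-D quadratic surrogate is minimized by solving

        ((gamma_v + kappa) G_m + lam_v1 D_v1 + lam_v2 D_v2^{(m)}) v
            = sum_c Y_m' z_c + Y_m' X u_m

    and rescaling v_m so ||Y_m v_m||^2 = 1.  ``kappa`` is 2 under the
    standard update rule (``regression_hessian="printed"``: the regression
    curvature enters once regardless of the number of scores), ``1 + C``
    under the fully derived regression Hessian (``"derived"``), and 1 with
    the regression switched off.

    ``cov_mode`` selects the curvature matrix G_m.  ``"identity"`` (the
    default) takes G_m = I, the usual simplification in this model family
    for column-standardized data; ``"exact"`` takes the full Gram matrix
    G_m = Y_m'Y_m.  See the methods notes for why the identity form is the
    default.
    """
    if regression_hessian not in ("printed", "derived"):
        raise ValueError("regression_hessian must be 'printed' or 'derived'")
    if cov_mode not in ("identity", "exact"):
        raise ValueError("cov_mode must be 'identity' or 'exact'")
    q, M = V_prev.shape
    C = Z.shape[1]
    diag = reweighting_diagonals(V=V_prev, eps=eps)
    if hyper.regression_on:
        kappa = 2.0 if regression_hessian == "printed" else 1.0 + C
        z_sum = Z.sum(axis=1)
    else:
        kappa = 1.0
    prenorm = np.empty_like(V_prev)
    V_new = np.empty_like(V_prev)
    for m, Y in enumerate(Ys):
        d = hyper.lambda_v1 * diag.d_v1 + hyper.lambda_v2 * diag.d_v2[:, m]
        b = Y.T @ (X @ U[:, m])
        if hyper.regression_on:
            b = b + Y.T @ z_sum
        if cov_mode == "identity":
            v = b / ((hyper.gamma_v + kappa) + d)
        else:
            G = gram_Ys[m] if gram_Ys is not None else Y.T @ Y
            A = (hyper.gamma_v + kappa) * G + np.diag(d)
            v = _solve_spd(A, b, "V")
        prenorm[:, m] = v
        scale = np.linalg.norm(Y @ v)
        if scale == 0:
            raise NumericalError("degenerate V update: Y v is the zero vector")
        V_new[:, m] = v / scale
    if return_prenorm:
        return V_new, prenorm
    return V_new


def update_u(
    X: np.ndarray,
    Ys: list[np.ndarray],
    V: np.ndarray,
    U_prev: np.ndarray,
    hyper: Hyperparameters,
    groups: GroupStructure | None = None,
    eps: float = DEFAULT_EPS,
    return_prenorm: bool = False,
    cov_mode: str = "identity",
    gram_X: np.ndarray | None = None,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """One reweighted half-step on the SNP-side weights U.

    With the projection stack columns Y_m v_m as targets, each task solves

        ((gamma_u + 1) G + lam_u1 D_u1 + lam_u2 D_u2^{(m)} + lam_u3 D_u3) u
            = X' Y_m v_m

    then rescales u_m so ||X u_m||^2 = 1.  The group diagonal D_u3 is only
    present when a group structure is supplied with lambda_u3 > 0.
    ``cov_mode`` selects the curvature matrix G as in :func:`update_v`:
    ``"identity"`` (default) or the exact Gram ``X'X``.
    """
    if cov_mode not in ("identity", "exact"):
        raise ValueError("cov_mode must be 'identity' or 'exact'")
    p, M = U_prev.shape
    if hyper.lambda_u3 > 0 and groups is None:
        raise ValueError("lambda_u3 > 0 requires a SNP group structure")
    diag = reweighting_diagonals(
        U=U_prev, groups=groups if hyper.lambda_u3 > 0 else None, eps=eps
    )
    base = hyper.lambda_u1 * diag.d_u1
    if diag.d_u3 is not None:
        base = base + hyper.lambda_u3 * diag.d_u3
    prenorm = np.empty_like(U_prev)
    U_new = np.empty_like(U_prev)
    for m, Y in enumerate(Ys):
        d = base + hyper.lambda_u2 * diag.d_u2[:, m]
        b = X.T @ (Y @ V[:, m])
        if cov_mode == "identity":
            u = b / ((hyper.gamma_u + 1.0) + d)
        else:
            G = gram_X if gram_X is not None else X.T @ X
            A = (hyper.gamma_u + 1.0) * G + np.diag(d)
            u = _solve_spd(A, b, "U")
        prenorm[:, m] = u
        scale = np.linalg.norm(X @ u)
        if scale == 0:
            raise NumericalError("degenerate U update: X u is the zero vector")
        U_new[:, m] = u / scale
    if return_prenorm:
        return U_new, prenorm
    return U_new


def _initial_weights(
    X: np.ndarray,
    Ys: list[np.ndarray],
    M: int,
    init: str,
    seed: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    p = X.shape[1]
    q = Ys[0].shape[1]
    if init == "constant":
        U0 = np.ones((p, M))
        V0 = np.ones((q, M))
    elif init == "random":
        rng = np.random.default_rng(seed)
        U0 = rng.standard_normal((p, M))
        V0 = rng.standard_normal((q, M))
    else:
        raise ValueError("init must be 'constant' or 'random'")
    for m in range(M):
        su = np.linalg.norm(X @ U0[:, m])
        sv = np.linalg.norm(Ys[m] @ V0[:, m])
        if su == 0 or sv == 0:
            raise NumericalError("degenerate initialization: zero projection")
        U0[:, m] /= su
        V0[:, m] /= sv
    return U0, V0


def fit(
    dataset: StudyDataset,
    hyper: Hyperparameters | None = None,
    max_iter: int = 200,
    tol: float = 1e-5,
    init: str = "constant",
    seed: int | None = None,
    eps: float = DEFAULT_EPS,
    regression_hessian: str = "printed",
    cov_mode: str = "identity",
) -> FitResult:
    """Fit MT-SCCAR by alternating reweighted half-steps.

    Expects a pre-conditioned dataset (standardized genotype and imaging
    columns, centered cognitive scores; :func:`mtsccar.assemble_dataset`
    and the synthetic generator produce these).  Each iteration refreshes
    the V diagonals, solves and normalizes every v_m, refreshes the U
    diagonals, then solves and normalizes every u_m.  The loop stops when
    both max|u^(t+1) - u^t| <= tol and max|v^(t+1) - v^t| <= tol (on the
    normalized iterates) or when ``max_iter`` is reached.

    With deterministic initialization (the default constant vectors) the
    result is bit-for-bit reproducible.
    """
    if hyper is None:
        hyper = Hyperparameters()
    X, Ys, Z = dataset.to_arrays()
    M = dataset.M
    groups = dataset.groups
    if hyper.lambda_u3 > 0 and groups is None:
        raise ValueError("lambda_u3 > 0 requires dataset.groups")

    U, V = _initial_weights(X, Ys, M, init, seed)
    exact = cov_mode == "exact"
    gram_X = X.T @ X if exact else None
    gram_Ys = [Y.T @ Y for Y in Ys] if exact else None

    obj_trace: list[float] = []
    max_violation = 0.0
    converged = False
    delta_u = delta_v = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        V_new = update_v(
            X, Ys, Z, U, V, hyper, eps=eps,
            regression_hessian=regression_hessian, cov_mode=cov_mode,
            gram_Ys=gram_Ys,
        )
        U_new = update_u(
            X, Ys, V_new, U, hyper, groups=groups, eps=eps,
            cov_mode=cov_mode, gram_X=gram_X,
        )
        if not (np.all(np.isfinite(U_new)) and np.all(np.isfinite(V_new))):
            raise NumericalError(f"non-finite weights at iteration {it}")
        delta_v = float(np.max(np.abs(V_new - V)))
        delta_u = float(np.max(np.abs(U_new - U)))
        U, V = U_new, V_new
        for m in range(M):
            max_violation = max(
                max_violation,
                abs(np.linalg.norm(X @ U[:, m]) ** 2 - 1.0),
                abs(np.linalg.norm(Ys[m] @ V[:, m]) ** 2 - 1.0),
            )
        obj_trace.append(objective(X, Ys, Z, U, V, hyper, groups=groups))
        if delta_u <= tol and delta_v <= tol:
            converged = True
            break

    ccc = np.empty(M)
    for m in range(M):
        a, b = X @ U[:, m], Ys[m] @ V[:, m]
        ccc[m] = np.corrcoef(a, b)[0, 1]

    weights = CanonicalWeights(
        U=U,
        V=V,
        snp_ids=list(dataset.genotypes.columns),
        qt_ids=list(dataset.modalities[0].columns),
        modality_names=list(dataset.modality_names),
    )
    return FitResult(
        weights=weights,
        converged=converged,
        n_iterations=it,
        objective_trace=np.asarray(obj_trace),
        per_task_training_ccc=ccc,
        max_constraint_violation=max_violation,
        final_delta_u=delta_u,
        final_delta_v=delta_v,
        hyper=hyper,
    )


def fit_mtscca(
    dataset: StudyDataset,
    hyper: Hyperparameters | None = None,
    max_iter: int = 200,
    tol: float = 1e-5,
    init: str = "constant",
    seed: int | None = None,
    eps: float = DEFAULT_EPS,
    cov_mode: str = "identity",
) -> FitResult:
    """Fit the unsupervised MTSCCA ablation (regression term removed).

    Identical to :func:`fit` with ``regression_on=False``; provided as the
    baseline against which the cognitive-score guidance is measured.
    """
    if hyper is None:
        hyper = Hyperparameters()
    return fit(
        dataset,
        hyper.replace(regression_on=False),
        max_iter=max_iter,
        tol=tol,
        init=init,
        seed=seed,
        eps=eps,
        cov_mode=cov_mode,
    )
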