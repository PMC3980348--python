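"""Windowed sparse-representation variable selection (SRVS).

The setting is a case/control phenotype ``y`` regressed on a design with
far more columns than samples (p >> n; once p exceeds roughly 35 n the
design cannot satisfy the restricted-isometry condition that classical
sparse recovery relies on).  Instead of solving one global sparse
regression, SRVS repeatedly

1. shuffles all p columns (Fisher-Yates) and partitions them into
   windows of length k,
2. sparse-codes y on each window with orthogonal matching pursuit (OMP)
   under the residual budget ``eps = tau_omp * ||y||_2``,
3. accumulates each window solution into a running coefficient vector,

and returns the running vector divided by the step count.  The window
length k sets the selection resolution: with k = p every step solves the
same full-design problem and at most n variables can come out; smaller
windows give weaker columns a chance to enter, so the support grows as k
shrinks, and the variables found at coarse resolution tend to reappear
at finer resolution.

:class:`SRVSSelector` wraps the procedure as a scikit-learn feature
selector; :func:`srvs_select` is the functional core.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeVector",
    "SRVSConfig",
    "WindowPlan",
    "WindowSolution",
    "SelectionResult",
    "omp_solve",
    "plan_windows",
    "srvs_select",
    "SRVSSelector",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class PhenotypeVector:
    """Per-sample numeric phenotype with its class labels.

    ``values`` is the numeric coding used in the regression (cases +1,
    controls -1 by convention); ``labels`` keeps the original class tags.
    """

    values: np.ndarray
    labels: np.ndarray
    sample_ids: list[str] | None = None
    coding: str = "case=+1, control=-1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.labels = np.asarray(self.labels)
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype contains non-finite values")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels and values lengths differ")
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != len(self.values):
                raise ValueError("sample_ids length mismatch")

    @classmethod
    def from_labels(
        cls,
        labels: Sequence[str],
        case_label: str = "case",
        control_label: str = "control",
        sample_ids: Sequence[str] | None = None,
    ) -> "PhenotypeVector":
        labels = np.asarray(labels)
        seen = set(np.unique(labels).tolist())
        expected = {case_label, control_label}
        if not seen <= expected:
            raise ValueError(
                f"unknown phenotype label(s) {sorted(seen - expected)}; "
                f"expected {sorted(expected)}"
            )
        values = np.where(labels == case_label, 1.0, -1.0)
        return cls(
            values=values,
            labels=labels,
            sample_ids=list(sample_ids) if sample_ids is not None else None,
            coding=f"{case_label}=+1, {control_label}=-1",
        )

    def require_two_classes(self) -> None:
        if np.unique(self.labels).size != 2:
            raise ValueError(
                "variable selection needs exactly two classes in the phenotype"
            )

    def take(self, rows: Sequence[int]) -> "PhenotypeVector":
        rows = np.asarray(rows, dtype=int)
        return PhenotypeVector(
            values=self.values[rows],
            labels=self.labels[rows],
            sample_ids=(
                [self.sample_ids[i] for i in rows] if self.sample_ids else None
            ),
            coding=self.coding,
        )

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class SRVSConfig:
    """Tunable parameters of a selection run.

    window_size : int or float
        Window length k; a float in (0, 1] is a fraction of p resolved
        before running (e.g. 0.05 -> k = round(0.05 p)).
    norm_order : {0, 1}
        Sparse penalty per window: 0 uses OMP, 1 a LARS/lasso homotopy
        path with the same stopping contract.
    omp_residual_frac : float
        tau of the per-window residual budget eps = tau * ||y||_2.
    convergence_tol : float
        Threshold on ``||d_l/l - d_{l-1}/(l-1)||_2`` below which the
        accumulation loop stops (checked once every column has been
        visited at least ``min_passes`` times).
    max_steps : int, optional
        Hard cap on window steps; defaults to ``50 * ceil(p / k)``
        (50 passes).  Reaching it reports non-convergence but still
        returns the averaged vector.
    """

    window_size: int | float = 0.1
    norm_order: int = 0
    omp_residual_frac: float = 0.3
    convergence_tol: float = 1e-3
    min_passes: int = 1
    max_steps: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.norm_order not in (0, 1):
            raise ValueError("norm_order must be 0 or 1")
        if not (0.0 <= self.omp_residual_frac <= 1.0):
            raise ValueError("omp_residual_frac must be in [0, 1]")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.min_passes < 1:
            raise ValueError("min_passes must be >= 1")

    def resolve_k(self, p: int) -> int:
        w = self.window_size
        if isinstance(w, float) and w <= 1.0:
            # fraction of p; 1.0 means the full design
            if w <= 0.0:
                raise ValueError(f"fractional window_size must be in (0, 1], got {w}")
            k = max(1, int(round(w * p)))
        else:
            if isinstance(w, float) and not w.is_integer():
                raise ValueError(f"window_size {w} is neither a fraction nor an integer")
            k = int(w)
        if not (1 <= k <= p):
            raise ValueError(f"window size k={k} outside [1, p={p}]")
        return k

    def resolve_max_steps(self, p: int, k: int) -> int:
        n_windows = -(-p // k)
        if self.max_steps is None:
            return 50 * n_windows
        if self.max_steps < self.min_passes * n_windows:
            raise ValueError(
                "max_steps must allow at least min_passes complete passes "
                f"({self.min_passes * n_windows} steps)"
            )
        return int(self.max_steps)


@dataclass
class WindowPlan:
    """One pass: a permutation of all p columns cut into blocks of <= k."""

    pass_permutation: np.ndarray
    windows: list[np.ndarray]


@dataclass
class WindowSolution:
    """Sparse code of y on one window's columns."""

    atom_indices: np.ndarray
    coefficients: np.ndarray
    residual_norm: float
    converged: bool = True


@dataclass
class SelectionResult:
    """Averaged accumulated coefficients delta = delta_l / l."""

    delta: np.ndarray
    steps: int
    change_history: np.ndarray
    support: np.ndarray = field(init=False)
    converged: bool = False
    n_passes: int = 0

    def __post_init__(self) -> None:
        self.support = np.flatnonzero(self.delta)


# ---------------------------------------------------------------------------
# solvers


def _validate_solver_inputs(columns: np.ndarray, target: np.ndarray) -> None:
    if not np.isfinite(columns).all():
        raise ValueError("design columns contain non-finite values")
    if not np.isfinite(target).all():
        raise ValueError("target contains non-finite values")


def omp_solve(
    columns: np.ndarray,
    target: np.ndarray,
    max_atoms: int,
    residual_eps: float,
    select_rule: str = "abs",
) -> WindowSolution:
    """Orthogonal matching pursuit on unit-norm (or zero) columns.

    Greedily adds the column most correlated with the current residual
    and least-squares refits on the whole selected support, stopping when
    the residual L2 norm drops to ``residual_eps``, ``max_atoms`` columns
    are active, or no column correlates with the residual at all.  The
    residual norm is non-increasing across iterations and the final
    residual is orthogonal to the span of the selected columns.

    ``select_rule="positive"`` picks atoms by largest positive (signed)
    correlation instead of largest magnitude; the coefficient refit stays
    unconstrained.  Used for classification coding where a sample must
    not be represented by the *negation* of the opposite class.
    """
    columns = np.asarray(columns, dtype=float)
    target = np.asarray(target, dtype=float).ravel()
    _validate_solver_inputs(columns, target)
    if columns.shape[0] != target.shape[0]:
        raise ValueError("columns and target row counts differ")
    if max_atoms < 1:
        raise ValueError("max_atoms must be >= 1")
    if residual_eps < 0:
        raise ValueError("residual_eps must be >= 0")
    if select_rule not in ("abs", "positive"):
        raise ValueError("select_rule must be 'abs' or 'positive'")

    k = columns.shape[1]
    n = columns.shape[0]
    max_atoms = min(max_atoms, k, n)
    rnorm = float(np.linalg.norm(target))
    atoms: list[int] = []
    coef = np.empty(0)
    if rnorm <= residual_eps or rnorm == 0.0:
        return WindowSolution(np.empty(0, dtype=int), coef, rnorm, True)

    # least-squares refit on the growing support via an incremental
    # Cholesky factor L of the selected Gram matrix: coefficients and the
    # residual follow from two triangular solves per iteration.
    from scipy.linalg import solve_triangular

    L = np.empty((max_atoms, max_atoms))
    z = np.empty(max_atoms)  # solve(L, A_s^T y); ||r||^2 = ||y||^2 - ||z||^2
    residual = target.copy()
    available = np.ones(k, dtype=bool)
    target_sq = float(target @ target)

    while len(atoms) < max_atoms:
        corr = columns.T @ residual
        corr[~available] = 0.0
        if select_rule == "abs":
            j = int(np.argmax(np.abs(corr)))
            if corr[j] == 0.0:
                break  # nothing selectable (e.g. all-zero columns)
        else:
            j = int(np.argmax(corr))
            if corr[j] <= 0.0:
                break  # no positively correlated atom left
        m = len(atoms)
        a_j = columns[:, j]
        if m == 0:
            d_sq = float(a_j @ a_j)
            w = np.empty(0)
        else:
            b = columns[:, atoms].T @ a_j
            w = solve_triangular(L[:m, :m], b, lower=True, check_finite=False)
            d_sq = float(a_j @ a_j) - float(w @ w)
        if d_sq <= 1e-12:
            break  # column (numerically) in the span of the support
        atoms.append(j)
        available[j] = False
        L[m, :m] = w
        L[m, m] = np.sqrt(d_sq)
        z[m] = (float(a_j @ target) - float(w @ z[:m])) / L[m, m]
        m += 1
        coef = solve_triangular(
            L[:m, :m].T, z[:m], lower=False, check_finite=False
        )
        residual = target - columns[:, atoms] @ coef
        rnorm = float(np.sqrt(max(target_sq - float(z[:m] @ z[:m]), 0.0)))
        if rnorm <= residual_eps:
            break

    if atoms:
        # final refit on the complete support for numerical stability on
        # ill-conditioned supports (the Cholesky recursion drives atom
        # choice and stopping; the returned coefficients are exact LS)
        sub = columns[:, atoms]
        coef, *_ = np.linalg.lstsq(sub, target, rcond=None)
        rnorm = float(np.linalg.norm(target - sub @ coef))
    return WindowSolution(
        atom_indices=np.asarray(atoms, dtype=int),
        coefficients=np.asarray(coef, dtype=float),
        residual_norm=rnorm,
        converged=rnorm <= residual_eps or len(atoms) == max_atoms,
    )


def lars_solve(
    columns: np.ndarray,
    target: np.ndarray,
    max_atoms: int,
    residual_eps: float,
) -> WindowSolution:
    """L1 variant: walk the lasso homotopy path until the residual budget
    or atom cap is met (same stopping contract as :func:`omp_solve`)."""
    from sklearn.linear_model import lars_path

    columns = np.asarray(columns, dtype=float)
    target = np.asarray(target, dtype=float).ravel()
    _validate_solver_inputs(columns, target)
    rnorm = float(np.linalg.norm(target))
    if rnorm <= residual_eps or rnorm == 0.0:
        return WindowSolution(np.empty(0, dtype=int), np.empty(0), rnorm, True)
    if not columns.any():
        return WindowSolution(np.empty(0, dtype=int), np.empty(0), rnorm, False)

    max_atoms = min(max_atoms, columns.shape[0], columns.shape[1])
    _, _, coefs = lars_path(columns, target, method="lasso", max_iter=10 * max_atoms)
    chosen = np.zeros(columns.shape[1])
    for step in range(coefs.shape[1]):
        beta = coefs[:, step]
        nnz = np.count_nonzero(beta)
        rn = float(np.linalg.norm(target - columns @ beta))
        if nnz <= max_atoms:
            chosen, rnorm = beta, rn
        if rn <= residual_eps or nnz >= max_atoms:
            break
    idx = np.flatnonzero(chosen)
    return WindowSolution(
        atom_indices=idx,
        coefficients=chosen[idx],
        residual_norm=rnorm,
        converged=rnorm <= residual_eps or idx.size >= max_atoms,
    )


def plan_windows(p: int, k: int, rng: np.random.Generator) -> WindowPlan:
    """Fisher-Yates shuffle of all p column indices, cut into blocks of k.

    Every column appears in exactly one window per pass; all blocks have
    size k except possibly the last.
    """
    if not 1 <= k <= p:
        raise ValueError(f"window length k={k} must satisfy 1 <= k <= p={p}")
    perm = rng.permutation(p)
    windows = [perm[i : i + k] for i in range(0, p, k)]
    return WindowPlan(pass_permutation=perm, windows=windows)


# ---------------------------------------------------------------------------
# the accumulation loop


def _prepare_target(y: np.ndarray) -> np.ndarray:
    """Center and unit-normalize the phenotype so eps and the convergence
    tolerance are scale-free."""
    y = np.asarray(y, dtype=float).ravel()
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains non-finite values")
    centered = y - y.mean()
    norm = np.linalg.norm(centered)
    if norm == 0:
        raise ValueError("phenotype is constant; nothing to regress on")
    return centered / norm


def srvs_select(
    design,
    phenotype,
    config: SRVSConfig,
) -> SelectionResult:
    """Run the windowed accumulation loop on a fused design.

    ``design`` is a :class:`~srvs.fusion.FusedDesign` or a plain
    (n, p) array whose columns are already normalized and weighted;
    ``phenotype`` is a :class:`PhenotypeVector` or numeric vector.
    Deterministic given ``config.seed``.
    """
    X = design.matrix if hasattr(design, "matrix") else np.asarray(design, dtype=float)
    if isinstance(phenotype, PhenotypeVector):
        phenotype.require_two_classes()
        y_raw = phenotype.values
    else:
        y_raw = np.asarray(phenotype, dtype=float)
    n, p = X.shape
    if y_raw.shape[0] != n:
        raise ValueError(f"phenotype length {y_raw.shape[0]} != design rows {n}")

    y = _prepare_target(y_raw)
    k = config.resolve_k(p)
    max_steps = config.resolve_max_steps(p, k)
    eps = config.omp_residual_frac  # ||y||_2 == 1 after normalization
    solver = omp_solve if config.norm_order == 0 else lars_solve
    rng = np.random.default_rng(config.seed)

    acc = np.zeros(p)
    acc_sq = 0.0  # running ||acc||^2, refreshed each pass against drift
    l = 0
    n_passes = 0
    changes: list[float] = []
    converged = False

    while l < max_steps and not converged:
        plan = plan_windows(p, k, rng)
        for win in plan.windows:
            l += 1
            sol = solver(X[:, win], y, max_atoms=min(n, win.size), residual_eps=eps)
            sel = win[sol.atom_indices]
            u = sol.coefficients
            if l >= 2:
                # ||acc_new/l - acc_old/(l-1)||^2 expanded on the sparse update
                prev_vals = acc[sel]
                u2 = float(u @ u)
                dot_pu = float(prev_vals @ u)
                lm1 = l - 1
                change_sq = (
                    u2 / l**2
                    - 2.0 * dot_pu / (l**2 * lm1)
                    + acc_sq / (l * lm1) ** 2
                )
                changes.append(float(np.sqrt(max(change_sq, 0.0))))
            if sel.size:
                prev_vals = acc[sel]
                acc_sq += 2.0 * float(prev_vals @ u) + float(u @ u)
                acc[sel] = prev_vals + u
            if (
                l >= 2
                and n_passes >= config.min_passes
                and changes[-1] <= config.convergence_tol
            ):
                converged = True
                break
            if l >= max_steps:
                break
        else:
            n_passes += 1
            acc_sq = float(acc @ acc)  # refresh against float drift
            continue
        break  # convergence or step cap reached mid-pass

    if not converged:
        warnings.warn(
            f"SRVS did not converge within {max_steps} steps "
            f"(last change {changes[-1] if changes else float('nan'):.3g} > "
            f"tol {config.convergence_tol:g}); returning the averaged vector",
            RuntimeWarning,
            stacklevel=2,
        )

    delta = acc / max(l, 1)
    return SelectionResult(
        delta=delta,
        steps=l,
        change_history=np.asarray(changes),
        converged=converged,
        n_passes=n_passes,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator


from sklearn.base import BaseEstimator  # noqa: E402
from sklearn.feature_selection import SelectorMixin  # noqa: E402
from sklearn.utils.validation import check_is_fitted, validate_data  # noqa: E402


class SRVSSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn feature selector running windowed sparse coding.

    Parameters mirror :class:`SRVSConfig`; in addition ``n_top`` keeps
    only the largest-amplitude coefficients and ``tau`` keeps the
    smallest prefix of the amplitude ranking whose truncated residual
    ``||y - X d||_2 / ||y||_2`` is below tau.  ``center``/``normalize``
    apply the standard per-column standardization to raw inputs; pass
    ``normalize=False`` for designs that are already column-normalized.

    Attributes
    ----------
    delta_ : ndarray of shape (n_features,)
        Averaged accumulated coefficient vector.
    support_indices_ : ndarray
        Indices retained by the selection rule, amplitude-ranked.
    n_steps_, n_passes_, converged_, change_history_ :
        Convergence diagnostics of the accumulation loop.
    """

    def __init__(
        self,
        window_size: int | float = 0.1,
        norm_order: int = 0,
        omp_residual_frac: float = 0.3,
        convergence_tol: float = 1e-3,
        min_passes: int = 1,
        max_steps: int | None = None,
        n_top: int | None = None,
        tau: float | None = None,
        center: bool = True,
        normalize: bool = True,
        random_state: int = 0,
    ) -> None:
        self.window_size = window_size
        self.norm_order = norm_order
        self.omp_residual_frac = omp_residual_frac
        self.convergence_tol = convergence_tol
        self.min_passes = min_passes
        self.max_steps = max_steps
        self.n_top = n_top
        self.tau = tau
        self.center = center
        self.normalize = normalize
        self.random_state = random_state

    def fit(self, X, y):
        from .sparsity import amplitude_ranking, truncated_residuals

        X, y = validate_data(self, X, y, dtype=float, ensure_min_samples=2)
        if self.n_top is not None and self.tau is not None:
            raise ValueError("set at most one of n_top and tau")
        Xw = X
        if self.center or self.normalize:
            centers = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
            shifted = X - centers
            if self.normalize:
                norms = np.linalg.norm(shifted, axis=0)
                safe = np.where(norms > 0, norms, 1.0)
                Xw = shifted / safe
                Xw[:, norms == 0] = 0.0
            else:
                Xw = shifted
        config = SRVSConfig(
            window_size=self.window_size,
            norm_order=self.norm_order,
            omp_residual_frac=self.omp_residual_frac,
            convergence_tol=self.convergence_tol,
            min_passes=self.min_passes,
            max_steps=self.max_steps,
            seed=self.random_state,
        )
        result = srvs_select(Xw, y, config)
        self.delta_ = result.delta
        self.n_steps_ = result.steps
        self.n_passes_ = result.n_passes
        self.converged_ = result.converged
        self.change_history_ = result.change_history

        ranked = amplitude_ranking(result.delta)
        if self.n_top is not None:
            keep = ranked[: self.n_top]
        elif self.tau is not None:
            taus = truncated_residuals(Xw, _prepare_target(y), result.delta, ranked)
            m = int(np.argmax(taus <= self.tau)) if (taus <= self.tau).any() else ranked.size
            keep = ranked[:m]
        else:
            keep = ranked
        self.support_indices_ = keep
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[keep] = True
        self.support_mask_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_
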