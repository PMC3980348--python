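"""Post-hoc sparsity control of an SRVS solution.

The averaged coefficient vector delta is dense on every column that ever
entered a window solution; its entry magnitudes rank the columns by how
much they contribute to representing the phenotype.  Two rules trim the
ranking: keep the top N amplitudes, or keep the shortest prefix whose
truncated representation already explains y to within a residual
fraction tau (``||y - X d^(m)||_2 <= tau * ||y||_2`` where ``d^(m)``
zeroes all but the m largest-amplitude entries).

The truncated residual deliberately uses the accumulated coefficients as
they are, with no least-squares refit on the retained support: with far
more retained columns than samples a refit would reach residual zero and
the curve would carry no information.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import SelectionResult, _prepare_target

logger = logging.getLogger(__name__)

__all__ = [
    "ResidualCurve",
    "amplitude_ranking",
    "truncated_residuals",
    "residual_curve",
    "select_by_tau",
    "select_top_n",
    "selection_overlap",
]


SELECTION_COLUMNS = ["rank", "modality", "variable_id", "global_index", "amplitude", "sign"]


def amplitude_ranking(delta: np.ndarray) -> np.ndarray:
    """Indices of the nonzero entries of delta, largest |delta| first.

    Ties broken by ascending column index (stable and reproducible).
    """
    delta = np.asarray(delta, dtype=float)
    support = np.flatnonzero(delta)
    order = np.argsort(-np.abs(delta[support]), kind="stable")
    return support[order]


def truncated_residuals(
    X: np.ndarray,
    y_unit: np.ndarray,
    delta: np.ndarray,
    ranked: np.ndarray,
    max_m: int | None = None,
) -> np.ndarray:
    """tau_m = ||y - X d^(m)||_2 / ||y||_2 for m = 0..len(ranked).

    ``y_unit`` must be the unit-normalized phenotype actually used in the
    selection run, so tau_0 == 1 exactly.
    """
    if max_m is not None:
        ranked = ranked[:max_m]
    residual = y_unit.copy()
    taus = np.empty(ranked.size + 1)
    norm0 = np.linalg.norm(residual)
    taus[0] = norm0
    for m, j in enumerate(ranked, start=1):
        residual -= X[:, j] * delta[j]
        taus[m] = np.linalg.norm(residual)
    return taus / norm0  # tau_0 exactly 1


class ResidualCurve:
    """Amplitude ranking of delta with the truncated-residual fractions.

    Attributes
    ----------
    ranked_indices : ndarray
        Global column indices sorted by |delta| descending.
    amplitudes : ndarray
        |delta| at those indices (non-increasing).
    tau_values : ndarray of length len(ranked_indices) + 1
        tau_m for m retained entries; tau_0 == 1.
    """

    def __init__(
        self,
        ranked_indices: np.ndarray,
        amplitudes: np.ndarray,
        tau_values: np.ndarray,
        coefficients: np.ndarray,
        column_map=None,
    ) -> None:
        if len(amplitudes) != len(ranked_indices):
            raise ValueError("amplitudes and ranked_indices lengths differ")
        if len(tau_values) != len(ranked_indices) + 1:
            raise ValueError("tau_values must have one entry per m = 0..support")
        if np.any(np.diff(amplitudes) > 1e-12):
            raise ValueError("amplitudes must be non-increasing")
        self.ranked_indices = np.asarray(ranked_indices, dtype=int)
        self.amplitudes = np.asarray(amplitudes, dtype=float)
        self.tau_values = np.asarray(tau_values, dtype=float)
        self.coefficients = np.asarray(coefficients, dtype=float)
        self.column_map = column_map

    def __len__(self) -> int:
        return self.ranked_indices.size

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per retained-count m (m = 0 row included)."""
        return pd.DataFrame(
            {
                "m": np.arange(self.tau_values.size),
                "global_index": np.concatenate(([-1], self.ranked_indices)),
                "amplitude": np.concatenate(([np.nan], self.amplitudes)),
                "tau": self.tau_values,
            }
        )


def _materialize(
    ranked: np.ndarray,
    delta: np.ndarray,
    column_map,
) -> pd.DataFrame:
    rows = []
    for rank, j in enumerate(ranked, start=1):
        tag, vid = column_map[j] if column_map is not None else ("modality", str(j))
        rows.append(
            {
                "rank": rank,
                "modality": tag,
                "variable_id": vid,
                "global_index": int(j),
                "amplitude": abs(float(delta[j])),
                "sign": int(np.sign(delta[j])),
            }
        )
    return pd.DataFrame(rows, columns=SELECTION_COLUMNS)


def residual_curve(
    design,
    phenotype,
    result: SelectionResult,
    max_m: int | None = None,
) -> ResidualCurve:
    """Truncated-residual curve of a finished selection run.

    ``design``/``phenotype`` must be the ones the run used.  ``max_m``
    caps the number of retained-count points (useful when the support is
    very large and only the head of the curve matters).
    """
    X = design.matrix if hasattr(design, "matrix") else np.asarray(design, dtype=float)
    y_raw = phenotype.values if hasattr(phenotype, "values") else np.asarray(phenotype)
    if result.delta.shape[0] != X.shape[1]:
        raise ValueError("delta length does not match design columns")
    y = _prepare_target(y_raw)  # raises on constant/zero phenotype

    ranked = amplitude_ranking(result.delta)
    if max_m is not None:
        ranked = ranked[:max_m]
    taus = truncated_residuals(X, y, result.delta, ranked)
    return ResidualCurve(
        ranked_indices=ranked,
        amplitudes=np.abs(result.delta[ranked]),
        tau_values=taus,
        coefficients=result.delta[ranked],
        column_map=getattr(design, "column_map", None),
    )


def select_by_tau(curve: ResidualCurve, tau: float) -> pd.DataFrame:
    """Smallest prefix of the ranking whose truncated residual is <= tau.

    Returns the selection table (rank, modality, variable_id,
    global_index, amplitude, sign).  If no prefix reaches tau the whole
    support is returned with a warning.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    within = curve.tau_values <= tau
    if within.any():
        m = int(np.argmax(within))
    else:
        m = len(curve)
        logger.warning(
            "no truncation reaches tau=%.3g (best %.3g); returning full support",
            tau,
            float(curve.tau_values.min()),
        )
    delta_like = np.zeros(int(curve.ranked_indices.max() + 1) if len(curve) else 1)
    delta_like[curve.ranked_indices] = curve.coefficients
    return _materialize(curve.ranked_indices[:m], delta_like, curve.column_map)


def select_top_n(
    result: SelectionResult,
    design,
    n_top: int,
) -> pd.DataFrame:
    """Top ``n_top`` variables by |delta| (ties: smaller column index first).

    If the support holds fewer than ``n_top`` nonzero entries, all of
    them are returned with a warning.
    """
    if n_top < 1:
        raise ValueError(f"n_top must be >= 1, got {n_top}")
    ranked = amplitude_ranking(result.delta)
    if ranked.size < n_top:
        logger.warning(
            "support has only %d nonzero entries (< n_top=%d); returning all",
            ranked.size,
            n_top,
        )
    return _materialize(
        ranked[:n_top], result.delta, getattr(design, "column_map", None)
    )


def selection_overlap(sel_a: pd.DataFrame, sel_b: pd.DataFrame) -> float:
    """|A ∩ B| / min(|A|, |B|) on (modality, variable_id) identities."""
    a = set(zip(sel_a["modality"], sel_a["variable_id"]))
    b = set(zip(sel_b["modality"], sel_b["variable_id"]))
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))
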