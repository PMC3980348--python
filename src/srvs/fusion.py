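"""Multimodal design construction.

Two modalities (e.g. a SNP genotype matrix coded 0/1/2 and a continuous
fMRI-voxel matrix) measured on the same samples are combined into one
design ``X = [a1*X1, a2*X2]`` with ``a1 + a2 = 1``: each modality's
columns are centered, scaled to unit L2 norm, multiplied by the modality
weight and concatenated.  The weight steers how many variables each
modality contributes to a sparse solution.  Bookkeeping maps every global
column back to its (modality, variable id) origin so selections can be
reported in modality terms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ModalityMatrix",
    "FusedDesign",
    "normalize_columns",
    "fuse",
    "build_design",
    "weight_grid",
]


@dataclass
class ModalityMatrix:
    """One modality's samples-by-variables numeric matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_variables)
        Numeric data; genotype matrices use additive 0/1/2 coding,
        imaging matrices are continuous.
    sample_ids, variable_ids : sequences of str
        Row and column identifiers. Variable ids must be unique within
        a modality.
    modality_tag : str
        Short name used in all outputs, e.g. ``"SNP"`` or ``"fMRI"``.
    """

    values: np.ndarray
    sample_ids: list[str]
    variable_ids: list[str]
    modality_tag: str = "modality"
    unselectable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x variables matrix")
        if not np.isfinite(self.values).all():
            raise ValueError(
                f"modality {self.modality_tag!r} contains non-finite entries"
            )
        n, p = self.values.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.variable_ids) != p:
            raise ValueError(
                f"{len(self.variable_ids)} variable ids for {p} columns"
            )
        if len(set(self.variable_ids)) != p:
            raise ValueError(
                f"duplicate variable ids in modality {self.modality_tag!r}"
            )
        if n < 2:
            raise ValueError("a modality needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def take_samples(self, rows: Sequence[int]) -> "ModalityMatrix":
        """Row subset (used by leave-one-out folds)."""
        rows = np.asarray(rows, dtype=int)
        return ModalityMatrix(
            values=self.values[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            variable_ids=list(self.variable_ids),
            modality_tag=self.modality_tag,
        )


@dataclass
class FusedDesign:
    """Weighted, column-normalized concatenation of one or two modalities.

    ``matrix[:, j]`` has L2 norm equal to the weight of its modality
    (columns that were constant before normalization are exactly zero and
    flagged in ``zero_mask``).  ``centers``/``scales`` hold the per-column
    affine transform fitted on the design's own samples so that held-out
    samples can be mapped into the same space (:meth:`transform_rows`).
    """

    matrix: np.ndarray
    weights: tuple[float, ...]
    tags: tuple[str, ...]
    column_map: list[tuple[str, str]]
    zero_mask: np.ndarray
    sample_ids: list[str]
    centers: np.ndarray
    scales: np.ndarray
    block_slices: dict[str, slice] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column_weights(self) -> np.ndarray:
        w = np.empty(self.n_columns)
        for tag, wt in zip(self.tags, self.weights):
            w[self.block_slices[tag]] = wt
        return w

    def transform_rows(self, rows_by_tag: dict[str, np.ndarray]) -> np.ndarray:
        """Map raw rows (one per modality) into the fused column space.

        Uses the centers/scales/weights fitted on the design's samples;
        this is what keeps leave-one-out folds honest: the held-out
        sample never influences the transform.
        """
        if set(rows_by_tag) != set(self.tags):
            raise ValueError(
                f"expected rows for modalities {self.tags}, got {tuple(rows_by_tag)}"
            )
        blocks = []
        w = self.column_weights()
        for tag in self.tags:
            sl = self.block_slices[tag]
            raw = np.atleast_2d(np.asarray(rows_by_tag[tag], dtype=float))
            if raw.shape[1] != sl.stop - sl.start:
                raise ValueError(
                    f"modality {tag!r}: expected {sl.stop - sl.start} values, "
                    f"got {raw.shape[1]}"
                )
            scales = self.scales[sl]
            safe = np.where(scales > 0, scales, 1.0)
            block = (raw - self.centers[sl]) / safe * w[sl]
            block[:, scales == 0] = 0.0
            blocks.append(block)
        return np.hstack(blocks)

    def split(self) -> dict[str, np.ndarray]:
        """Undo weighting: per-modality blocks with unit-norm columns."""
        out = {}
        for tag, wt in zip(self.tags, self.weights):
            out[tag] = self.matrix[:, self.block_slices[tag]] / wt
        return out


def _center_scale(values: np.ndarray, center: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centers = values.mean(axis=0) if center else np.zeros(values.shape[1])
    shifted = values - centers
    norms = np.linalg.norm(shifted, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    out = shifted / safe
    out[:, norms == 0] = 0.0
    return out, centers, norms


def normalize_columns(m: ModalityMatrix, center: bool = True) -> ModalityMatrix:
    """Scale every column to unit L2 norm (after optional mean-centering).

    Columns that are exactly zero — or constant, hence zero after
    centering (e.g. monomorphic SNPs) — are left as zero and flagged
    unselectable rather than dropped, so column indices stay stable.
    """
    normed, _, norms = _center_scale(m.values, center)
    zero = norms == 0
    if zero.any():
        logger.warning(
            "modality %r: %d constant column(s) flagged unselectable",
            m.modality_tag,
            int(zero.sum()),
        )
    return ModalityMatrix(
        values=normed,
        sample_ids=list(m.sample_ids),
        variable_ids=list(m.variable_ids),
        modality_tag=m.modality_tag,
        unselectable=zero,
    )


def build_design(
    m1: ModalityMatrix,
    m2: ModalityMatrix | None = None,
    alpha1: float | None = None,
    center: bool = True,
) -> FusedDesign:
    """Build the fused design from one or two modalities.

    With a single modality the weight is 1. With two, ``alpha1`` in (0, 1)
    weights the first block and ``1 - alpha1`` the second.
    """
    if m2 is None:
        mods = [m1]
        weights = (1.0,)
    else:
        if alpha1 is None:
            alpha1 = 0.5
        if not (0.0 < alpha1 < 1.0):
            raise ValueError(f"alpha1 must be in (0, 1), got {alpha1}")
        if m1.sample_ids != m2.sample_ids:
            raise ValueError(
                "modalities must share the same samples in the same order"
            )
        if m1.modality_tag == m2.modality_tag:
            raise ValueError("modalities must carry distinct tags")
        mods = [m1, m2]
        weights = (float(alpha1), float(1.0 - alpha1))

    blocks, centers, scales, column_map, zero_flags = [], [], [], [], []
    slices: dict[str, slice] = {}
    start = 0
    for m, w in zip(mods, weights):
        normed, c, s = _center_scale(m.values, center)
        zero = s == 0
        if zero.any():
            logger.warning(
                "modality %r: %d constant column(s) flagged unselectable",
                m.modality_tag,
                int(zero.sum()),
            )
        blocks.append(normed * w)
        centers.append(c)
        scales.append(s)
        zero_flags.append(zero)
        column_map.extend((m.modality_tag, v) for v in m.variable_ids)
        slices[m.modality_tag] = slice(start, start + m.n_variables)
        start += m.n_variables

    matrix = np.asfortranarray(np.hstack(blocks))
    return FusedDesign(
        matrix=matrix,
        weights=weights,
        tags=tuple(m.modality_tag for m in mods),
        column_map=column_map,
        zero_mask=np.concatenate(zero_flags),
        sample_ids=list(m1.sample_ids),
        centers=np.concatenate(centers),
        scales=np.concatenate(scales),
        block_slices=slices,
    )


def fuse(
    m1: ModalityMatrix,
    m2: ModalityMatrix,
    alpha1: float,
    center: bool = True,
) -> FusedDesign:
    """Two-modality design ``[alpha1 * X1, (1 - alpha1) * X2]``."""
    return build_design(m1, m2, alpha1=alpha1, center=center)


def weight_grid(lo: float, hi: float, step: float) -> list[float]:
    """Inclusive grid of first-modality weights, e.g. 0.30, 0.32, ..., 0.60.

    Computed in exact decimal steps so no value suffers floating-point
    accumulation; (hi - lo) must be an integer multiple of step.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    try:
        dlo, dhi, dstep = (Decimal(str(v)) for v in (lo, hi, step))
    except InvalidOperation as exc:  # pragma: no cover - defensive
        raise ValueError(f"bad grid spec ({lo}, {hi}, {step})") from exc
    ratio = (dhi - dlo) / dstep
    nearest = int(ratio.to_integral_value())
    if abs(float(ratio - nearest)) * float(dstep) > 1e-9:
        raise ValueError(
            f"grid span {hi} - {lo} is not an integer multiple of step {step}"
        )
    return [float(dlo + i * dstep) for i in range(nearest + 1)]
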