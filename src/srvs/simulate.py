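"""Synthetic case/control data with known ground truth.

Two designs:

* a pure white-noise null (i.i.d. standard normal entries, balanced
  case/control labels carrying no signal) used to study how the window
  length and the residual budget shape the selection when nothing is
  there to find;
* planted-signal data — continuous columns whose class means differ by a
  chosen effect size in noise-SD units, or additive 0/1/2 genotype
  columns whose case allele frequency is shifted — used for recovery and
  classification tests where the informative columns are known by
  construction.

Generation is chunked column-wise with a counter-based seeding scheme:
each fixed-width column chunk gets its own generator keyed on
``(seed, stream, chunk)``, so a matrix with a million columns can be
produced incrementally and regeneration with the same seed is
bit-identical regardless of available memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PhenotypeVector
from .fusion import ModalityMatrix

__all__ = [
    "SyntheticDataset",
    "gen_white_noise",
    "gen_planted",
    "gen_planted_multimodal",
]

_CHUNK = 16384  # columns per generation chunk; fixed so results never
# depend on how much is generated at once
_MAX_ENTRIES = 2**31  # beyond this a dense in-memory matrix is refused

TRUTH_COLUMNS = ["modality", "variable_id", "column_index", "effect"]


@dataclass
class SyntheticDataset:
    modality1: ModalityMatrix
    phenotype: PhenotypeVector
    modality2: ModalityMatrix | None = None
    truth: pd.DataFrame | None = None
    seed: int = 0

    def modalities(self) -> list[ModalityMatrix]:
        out = [self.modality1]
        if self.modality2 is not None:
            out.append(self.modality2)
        return out


def _phenotype(n_case: int, n_control: int) -> PhenotypeVector:
    if n_case < 1 or n_control < 1:
        raise ValueError("need at least one case and one control")
    labels = np.array(["case"] * n_case + ["control"] * n_control)
    ids = [f"S{i:04d}" for i in range(n_case + n_control)]
    return PhenotypeVector.from_labels(labels, sample_ids=ids)


def _check_size(n: int, p: int) -> None:
    if n < 1 or p < 1:
        raise ValueError("sample and variable counts must be >= 1")
    if n * p > _MAX_ENTRIES:
        raise ValueError(
            f"{n} x {p} = {n * p} entries exceeds the dense in-memory limit "
            f"({_MAX_ENTRIES}); generate in column blocks by calling the "
            "generator on sub-ranges of variables"
        )


def _chunked_normal(n: int, p: int, seed: int, stream: int) -> np.ndarray:
    out = np.empty((n, p), order="F")
    for c, start in enumerate(range(0, p, _CHUNK)):
        stop = min(start + _CHUNK, p)
        rng = np.random.default_rng(np.random.SeedSequence([seed, stream, c]))
        out[:, start:stop] = rng.standard_normal((n, stop - start))
    return out


def gen_white_noise(
    n_case: int,
    n_control: int,
    p: int,
    seed: int = 0,
    tag: str = "noise",
) -> SyntheticDataset:
    """Null dataset: i.i.d. N(0, 1) entries, labels carry no signal."""
    phenotype = _phenotype(n_case, n_control)
    n = n_case + n_control
    _check_size(n, p)
    values = _chunked_normal(n, p, seed, stream=0)
    m = ModalityMatrix(
        values=values,
        sample_ids=[f"S{i:04d}" for i in range(n)],
        variable_ids=[f"{tag}_v{j}" for j in range(p)],
        modality_tag=tag,
    )
    return SyntheticDataset(
        modality1=m,
        phenotype=phenotype,
        truth=pd.DataFrame(columns=TRUTH_COLUMNS),
        seed=seed,
    )


def gen_planted(
    n_case: int,
    n_control: int,
    p: int,
    q_signal: int,
    effect: float,
    kind: str = "continuous",
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    tag: str | None = None,
    _stream: int = 1,
) -> SyntheticDataset:
    """Case/control matrix with ``q_signal`` informative columns.

    continuous
        Unit-variance Gaussian noise; on signal columns the case mean is
        shifted by +effect/2 and the control mean by -effect/2, so the
        between-class difference equals ``effect`` noise SDs (Cohen's d).
    genotype
        Additive-coded counts drawn Binomial(2, f) per column under
        Hardy-Weinberg, with column allele frequency f uniform in
        ``maf_range``; on signal columns the case frequency is shifted by
        ``effect`` (must stay inside (0, 1)).
    """
    phenotype = _phenotype(n_case, n_control)
    n = n_case + n_control
    _check_size(n, p)
    if not 0 <= q_signal <= p:
        raise ValueError("q_signal must be in [0, p]")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    if kind not in ("continuous", "genotype"):
        raise ValueError(f"kind must be 'continuous' or 'genotype', got {kind!r}")
    tag = tag or kind
    rng = np.random.default_rng(np.random.SeedSequence([seed, _stream, 999]))
    signal_idx = np.sort(rng.choice(p, size=q_signal, replace=False))
    case_rows = np.arange(n_case)
    control_rows = np.arange(n_case, n)

    if kind == "continuous":
        values = _chunked_normal(n, p, seed, stream=_stream)
        values[np.ix_(case_rows, signal_idx)] += effect / 2.0
        values[np.ix_(control_rows, signal_idx)] -= effect / 2.0
        effects = np.full(q_signal, effect, dtype=float)
    else:
        lo, hi = maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if hi + effect >= 1.0:
            raise ValueError(
                f"allele-frequency shift {effect} can push frequency past 1 "
                f"for maf up to {hi}"
            )
        freqs = rng.uniform(lo, hi, size=p)
        values = np.empty((n, p), order="F")
        for c, start in enumerate(range(0, p, _CHUNK)):
            stop = min(start + _CHUNK, p)
            crng = np.random.default_rng(np.random.SeedSequence([seed, _stream, c]))
            f = np.broadcast_to(freqs[start:stop], (n, stop - start)).copy()
            values[:, start:stop] = crng.binomial(2, f)
        if q_signal:
            srng = np.random.default_rng(np.random.SeedSequence([seed, _stream, 1000]))
            f_case = np.clip(freqs[signal_idx] + effect, 1e-9, 1 - 1e-9)
            values[np.ix_(case_rows, signal_idx)] = srng.binomial(
                2, np.broadcast_to(f_case, (n_case, q_signal))
            )
        effects = np.full(q_signal, effect, dtype=float)

    variable_ids = [f"{tag}_v{j}" for j in range(p)]
    m = ModalityMatrix(
        values=values,
        sample_ids=[f"S{i:04d}" for i in range(n)],
        variable_ids=variable_ids,
        modality_tag=tag,
    )
    truth = pd.DataFrame(
        {
            "modality": tag,
            "variable_id": [variable_ids[j] for j in signal_idx],
            "column_index": signal_idx,
            "effect": effects,
        },
        columns=TRUTH_COLUMNS,
    )
    return SyntheticDataset(
        modality1=m,
        phenotype=phenotype,
        truth=truth,
        seed=seed,
    )


def gen_planted_multimodal(
    n_case: int,
    n_control: int,
    p1: int,
    q1: int,
    effect1: float,
    p2: int,
    q2: int,
    effect2: float,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
) -> SyntheticDataset:
    """Two modalities over the same samples: a genotype block (tag "SNP")
    and a continuous block (tag "fMRI"), each with planted signal."""
    snp = gen_planted(
        n_case, n_control, p1, q1, effect1,
        kind="genotype", maf_range=maf_range, seed=seed, tag="SNP", _stream=1,
    )
    img = gen_planted(
        n_case, n_control, p2, q2, effect2,
        kind="continuous", seed=seed, tag="fMRI", _stream=2,
    )
    truth = pd.concat([snp.truth, img.truth], ignore_index=True)
    return SyntheticDataset(
        modality1=snp.modality1,
        modality2=img.modality1,
        phenotype=snp.phenotype,
        truth=truth,
        seed=seed,
    )
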