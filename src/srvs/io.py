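"""Plain-text readers and writers.

Matrices travel as delimited text (TSV or CSV by extension): a header
row of variable ids, a first column of sample ids, numeric body.  The
PLINK ``.raw`` additive-recode dialect (FID/IID/PAT/MAT/SEX/PHENOTYPE
leading columns, 0/1/2 genotype codes) is accepted behind a flag.
Phenotypes are two-column sample_id/label tables.  Every writer prepends
a ``#``-commented provenance header (package version, seed, config) and
every reader skips such comments, so write-then-read round-trips are
exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .core import PhenotypeVector
from .fusion import ModalityMatrix

__all__ = [
    "read_matrix",
    "read_phenotype",
    "write_matrix",
    "write_phenotype",
    "write_table",
    "read_table",
    "write_json_summary",
]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def provenance_lines(seed: int | None = None, config: Mapping | None = None) -> list[str]:
    lines = [f"# srvs {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config:
        lines.append(f"# config: {json.dumps(dict(config), sort_keys=True, default=str)}")
    return lines


def _fail_on_na(df: pd.DataFrame, path: Path) -> None:
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        spots = ", ".join(
            f"(sample {df.index[r]!r}, variable {df.columns[c]!r})"
            for r, c in list(zip(rows, cols))[:5]
        )
        raise ValueError(f"{path}: missing values at {spots}")


def read_matrix(
    path: str | Path,
    modality_tag: str | None = None,
    plink_raw: bool = False,
) -> ModalityMatrix:
    """Read a samples-by-variables matrix from delimited text.

    Errors name the offending location (NA cells, duplicate ids,
    non-numeric entries).
    """
    path = Path(path)
    if plink_raw:
        df = pd.read_csv(path, sep=r"\s+", comment="#", dtype={"IID": str, "FID": str},
                         float_precision="round_trip")
        missing = [c for c in _PLINK_META if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: not PLINK .raw (missing columns {missing})")
        sample_ids = df["IID"].astype(str).tolist()
        body = df.drop(columns=_PLINK_META)
        body.index = sample_ids
    else:
        df = pd.read_csv(path, sep=_sep_for(path), comment="#", index_col=0,
                         float_precision="round_trip")
        body = df
        body.index = body.index.astype(str)

    _fail_on_na(body, path)
    if body.index.duplicated().any():
        dupes = body.index[body.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    if body.columns.duplicated().any():
        dupes = body.columns[body.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate variable ids {dupes}")
    try:
        values = body.to_numpy(dtype=float)
    except ValueError:
        for col in body.columns:
            bad = pd.to_numeric(body[col], errors="coerce").isna() & body[col].notna()
            if bad.any():
                raise ValueError(
                    f"{path}: non-numeric value {body.loc[bad, col].iloc[0]!r} "
                    f"at (sample {body.index[bad][0]!r}, variable {col!r})"
                ) from None
        raise
    return ModalityMatrix(
        values=values,
        sample_ids=body.index.tolist(),
        variable_ids=[str(c) for c in body.columns],
        modality_tag=modality_tag or path.stem,
    )


def read_phenotype(
    path: str | Path,
    sample_ids: list[str] | None = None,
    case_label: str = "case",
    control_label: str = "control",
) -> PhenotypeVector:
    """Read a two-column (sample_id, label) table; optionally reorder to
    match a design's sample order."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (sample_id, label), got {df.shape[1]}")
    df.columns = ["sample_id", "label"]
    _fail_on_na(df, path)
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    if sample_ids is not None:
        have = dict(zip(df["sample_id"], df["label"]))
        missing = [s for s in sample_ids if s not in have]
        if missing:
            raise ValueError(f"{path}: no phenotype for sample(s) {missing[:5]}")
        ordered = pd.DataFrame(
            {"sample_id": sample_ids, "label": [have[s] for s in sample_ids]}
        )
    else:
        ordered = df
    return PhenotypeVector.from_labels(
        ordered["label"].to_numpy(),
        case_label=case_label,
        control_label=control_label,
        sample_ids=ordered["sample_id"].tolist(),
    )


def _write_with_header(text: str, path: Path, seed, config) -> None:
    header = "\n".join(provenance_lines(seed, config))
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(header + "\n" + text)


def write_matrix(
    m: ModalityMatrix,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    path = Path(path)
    df = pd.DataFrame(m.values, index=m.sample_ids, columns=m.variable_ids)
    df.index.name = "sample_id"
    # %.17g guarantees float round-trip to the bit
    _write_with_header(
        df.to_csv(sep=_sep_for(path), float_format="%.17g"), path, seed, config
    )


def write_phenotype(
    ph: PhenotypeVector,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    path = Path(path)
    ids = ph.sample_ids or [str(i) for i in range(len(ph))]
    df = pd.DataFrame({"sample_id": ids, "label": ph.labels})
    _write_with_header(df.to_csv(sep=_sep_for(path), index=False), path, seed, config)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    """Write any tidy table (selection, residual curve, truth, CR folds)."""
    path = Path(path)
    _write_with_header(
        df.to_csv(sep=_sep_for(path), index=False, float_format="%.17g"),
        path,
        seed,
        config,
    )


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), comment="#", float_precision="round_trip")


def write_json_summary(payload: Mapping, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(payload)
    payload.setdefault("srvs_version", __version__)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
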