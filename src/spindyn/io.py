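"""Tabular I/O: TSV schemas shared by all pipeline stages, run manifests.

Every writer emits plain TSV with a fixed header and stable float
formatting, so rerunning a stage on unchanged inputs reproduces its
outputs byte for byte; every reader validates the header and reports
missing columns by name.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .context import SpectrometerContext
from .modelfree import ModelFit, ResidueRelaxationRecord

DECAY_COLUMNS = ["residue", "experiment", "replicate", "delay_s", "height"]
RATE_COLUMNS = ["residue", "R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err"]
MODELFREE_COLUMNS = [
    "residue", "model", "S2", "S2_err", "te_ns", "te_err", "rex", "rex_err", "chi2",
]
TRUTH_COLUMNS = ["residue", "name", "region", "model", "S2", "te_ns", "rex"]


class SchemaError(ValueError):
    """Raised when a table does not match its expected column schema."""


def _validate(frame: pd.DataFrame, columns: Sequence[str], what: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns: {', '.join(missing)}")
    if len(frame) == 0:
        raise SchemaError(f"{what} table contains no data rows")
    return frame


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="")


def read_decay_table(path: str | Path) -> pd.DataFrame:
    return _validate(pd.read_csv(path, sep="\t"), DECAY_COLUMNS, "decay")


def read_rate_table(path: str | Path) -> pd.DataFrame:
    return _validate(pd.read_csv(path, sep="\t"), RATE_COLUMNS, "rate")


def read_modelfree_table(path: str | Path) -> pd.DataFrame:
    return _validate(pd.read_csv(path, sep="\t"), MODELFREE_COLUMNS, "model-free results")


def records_from_rate_table(
    rates: pd.DataFrame, context: SpectrometerContext
) -> list[ResidueRelaxationRecord]:
    """Per-residue records from a rate table; rows with NaNs are skipped."""
    _validate(rates, RATE_COLUMNS, "rate")
    records = []
    for row in rates.itertuples():
        values = [row.R1, row.R1_err, row.R2, row.R2_err, row.NOE, row.NOE_err]
        if any(v is None or not np.isfinite(v) for v in values):
            continue
        records.append(
            ResidueRelaxationRecord(
                residue_id=int(row.residue),
                r1=row.R1, r1_err=row.R1_err,
                r2=row.R2, r2_err=row.R2_err,
                noe=row.NOE, noe_err=row.NOE_err,
                context=context,
            )
        )
    return records


def modelfree_frame(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """Model-free results table from per-residue fits."""
    rows = []
    for fit in fits:
        p = fit.params
        sig = fit.mc_sigmas
        rows.append(
            {
                "residue": fit.residue_id,
                "model": p.model_id,
                "S2": p.s2,
                "S2_err": sig.get("s2", np.nan),
                "te_ns": p.te_s * 1e9,
                "te_err": sig.get("te", np.nan) * 1e9 if "te" in sig else np.nan,
                "rex": p.rex,
                "rex_err": sig.get("rex", np.nan),
                "chi2": fit.chi2,
            }
        )
    return pd.DataFrame(rows, columns=MODELFREE_COLUMNS)


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
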