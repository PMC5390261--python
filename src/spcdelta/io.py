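"""TSV/JSON file contracts for the pipeline.

All tables travel as plain TSV.  The count-matrix dialect is: header row of
sample ids encoded ``condition.compartment.bioN.techM``, first column the
protein accessions, integer cells.  Floating-point results are printed at 6
significant digits, so a write-read round trip reproduces values to print
precision (and calls exactly).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .quantitation import CountMatrix, parse_sample_id

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_table",
    "write_table",
    "write_results_table",
    "read_results_table",
    "PipelineConfig",
]

RESULT_COLUMNS = [
    "accession",
    "compartment",
    "n_ctrl",
    "t_ctrl",
    "n_kd",
    "t_kd",
    "rsc",
    "p_raw",
    "q_bh",
    "call",
]
_FLOAT_COLUMNS = ("rsc", "p_raw", "q_bh")


def read_count_matrix(path) -> CountMatrix:
    """Parse a count-matrix TSV, validating ids, integrality and sign.

    Parse errors name the offending row/column.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    for sample_id in frame.columns:
        parse_sample_id(sample_id)  # raises with the malformed id
    if frame.index.duplicated().any():
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate accession(s) in {path}: {dups}")
    for col in frame.columns:
        values = frame[col]
        if values.isna().any():
            row = values.index[values.isna()][0]
            raise ValueError(f"missing cell in {path} at row {row!r}, column {col!r}")
        try:
            as_int = values.astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-integer cell in {path}, column {col!r}") from exc
        if not (values == as_int).all():
            row = values.index[values != as_int][0]
            raise ValueError(f"non-integer cell in {path} at row {row!r}, column {col!r}")
        if (as_int < 0).any():
            row = as_int.index[as_int < 0][0]
            raise ValueError(f"negative count in {path} at row {row!r}, column {col!r}")
        frame[col] = as_int
    return CountMatrix(frame)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="accession")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_results_table(results: pd.DataFrame, path) -> None:
    """Write a differential-results table with fixed column order and floats
    at 6 significant digits.  An empty table yields a header-only file."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    out = results[cols].copy()
    for col in _FLOAT_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    for col in _FLOAT_COLUMNS:
        if col in frame.columns:
            frame[col] = frame[col].astype(float)
    return frame


@dataclasses.dataclass
class PipelineConfig:
    """Driver configuration: either a simulation block or input paths.

    Thresholds default to the analysis' documented values: PSM probability
    > 0.95, protein probability > 0.99 with >= 2 unique peptides and decoy
    FDR <= 1%, Rsc pseudocount f = 0.5, |Rsc| > 1.8 and BH-adjusted
    significance < 0.05.
    """

    outdir: str = "spcdelta_out"
    seed: int = 0
    # exactly one of the two input modes
    simulation: dict | None = None
    counts_path: str | None = None
    proteins_path: str | None = None
    psms_path: str | None = None
    category_map_path: str | None = None
    # thresholds
    min_probability: float = 0.95
    min_protein_probability: float = 0.99
    min_unique_peptides: int = 2
    max_fdr: float = 0.01
    f: float = 0.5
    rsc_threshold: float = 1.8
    alpha: float = 0.05
    use_adjusted: bool = True
    conditions: tuple[str, str] = ("control", "kd")

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.counts_path is None):
            raise ValueError("exactly one of a simulation block or a counts path is required")
        for name in ("min_probability", "min_protein_probability", "max_fdr", "alpha"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.f <= 0 or self.rsc_threshold < 0 or self.min_unique_peptides < 0:
            raise ValueError("f must be positive; thresholds must be non-negative")
        self.conditions = tuple(self.conditions)  # type: ignore[assignment]

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            payload = json.load(handle)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["conditions"] = list(self.conditions)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
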