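"""Table readers/writers and run configuration.

Accepted abundance-table dialects:

* **wide** — first column ``peptidoform`` (row descriptors, see
  :mod:`hptmkit.quantify` for the grammar), remaining columns one sample each
  named ``P<passage>_R<replicate>``.
* **long** — three columns ``peptidoform``, ``sample``, ``abundance``.

Decimal points only ('.'); locale commas are rejected rather than silently
misparsed.  Blank/unparseable numeric cells become missing values and are
counted in the log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import AbundanceMatrix, RAMatrix

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "write_ra_matrix",
    "read_protein_table",
    "RunConfig",
]

logger = logging.getLogger(__name__)

_COMMA_DECIMAL_RE = re.compile(r"^-?\d+,\d+$")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _to_float(cell, bad: list) -> float:
    if cell is None:
        return np.nan
    s = str(cell).strip()
    if s == "" or s.lower() in {"na", "nan"}:
        return np.nan
    if _COMMA_DECIMAL_RE.match(s):
        raise ValueError(
            f"cell {s!r} uses a comma decimal; re-export the table with '.' decimals"
        )
    try:
        return float(s)
    except ValueError:
        bad.append(s)
        return np.nan


def _numeric(frame: pd.DataFrame, what: str) -> pd.DataFrame:
    bad: list = []
    out = frame.map(lambda c: _to_float(c, bad))
    if bad:
        logger.warning("%s: %d unparseable cell(s) treated as missing", what, len(bad))
    return out


def read_abundance_table(
    path, dialect: str = "wide", normalization_tag: str = "as-imported"
) -> AbundanceMatrix:
    """Read a CSV/TSV peptidoform abundance table (wide or long dialect)."""
    path = Path(path)
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if raw.empty or raw.shape[1] < 2:
        raise ValueError(f"{path}: empty or column-less abundance table")
    if dialect == "wide":
        if raw.columns[0] != "peptidoform":
            raise ValueError(f"{path}: wide tables must start with a 'peptidoform' column")
        dup = raw["peptidoform"][raw["peptidoform"].duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"{path}: duplicate peptidoform rows: {dup}")
        values = _numeric(raw.set_index("peptidoform"), str(path))
    elif dialect == "long":
        need = {"peptidoform", "sample", "abundance"}
        if not need <= set(raw.columns):
            raise ValueError(f"{path}: long tables need columns {sorted(need)}")
        dup = raw.duplicated(subset=["peptidoform", "sample"])
        if dup.any():
            pairs = raw.loc[dup, ["peptidoform", "sample"]].to_records(index=False)
            raise ValueError(f"{path}: duplicate (peptidoform, sample) rows: {list(pairs)}")
        bad: list = []
        raw = raw.assign(abundance=[_to_float(c, bad) for c in raw["abundance"]])
        if bad:
            logger.warning("%s: %d unparseable cell(s) treated as missing", path, len(bad))
        values = raw.pivot(index="peptidoform", columns="sample", values="abundance")
        values.columns.name = None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    values.index.name = None
    return AbundanceMatrix.from_wide(values, normalization_tag=normalization_tag)


def write_abundance_table(matrix: AbundanceMatrix, path) -> None:
    path = Path(path)
    out = matrix.values.copy()
    out.insert(0, "peptidoform", out.index)
    out.to_csv(path, sep=_sep_for(path), index=False)


def write_ra_matrix(ra: RAMatrix, path) -> None:
    """Write an RA matrix as TSV (rows = hPTM keys, columns = samples)."""
    path = Path(path)
    out = ra.values.copy()
    out.insert(0, "hptm", out.index)
    out.to_csv(path, sep=_sep_for(path), index=False)


def read_protein_table(path) -> pd.DataFrame:
    """Read a protein x sample abundance table (first column = protein id)."""
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if raw.empty or raw.shape[1] < 2:
        raise ValueError(f"{path}: empty or column-less protein table")
    return _numeric(raw.set_index(raw.columns[0]), str(path))


_KNOWN_CONFIG_KEYS = {
    "seed",
    "passages",
    "replicates",
    "ppm_tolerance",
    "alpha_timecourse",
    "alpha_endpoint",
    "endpoint_start",
    "endpoint_end",
    "equal_var",
    "merge_h3_variants",
    "merge_k36_k37",
    "abundance_table",
    "dialect",
    "log_level",
}


@dataclass
class RunConfig:
    """Pipeline run configuration; unknown keys are rejected on load."""

    seed: int = 0
    passages: tuple[str, ...] = ("P0", "P3", "P6", "P9", "P12")
    replicates: int = 4
    ppm_tolerance: float = 10.0
    alpha_timecourse: float = 0.05
    alpha_endpoint: float = 0.01
    endpoint_start: str = "P0"
    endpoint_end: str = "P12"
    equal_var: bool = True
    merge_h3_variants: bool = False
    merge_k36_k37: bool = False
    abundance_table: str | None = None
    dialect: str = "wide"
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        unknown = set(data) - _KNOWN_CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "passages" in data:
            data["passages"] = tuple(data["passages"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["passages"] = list(d["passages"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
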