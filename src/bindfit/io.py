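"""Unit-tagged tabular IO and machine-readable result reports.

CSV columns carry their unit in the header suffix (``conc_uM``, ``time_s``,
``temp_C``, ``shift_nm`` ...).  Readers normalise everything to the
package's internal units — molar, seconds, degC at the thermal boundary —
and refuse unrecognised tags instead of silently coercing.  Reports are
versioned JSON with a provenance block (input hash, seed, package version)
sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "UNIT_FACTORS",
    "ResultReport",
    "split_unit_tag",
    "read_table",
    "write_table",
    "sha256_file",
]

REPORT_SCHEMA_VERSION = "1.0"

#: multiplicative factor to the internal unit, per recognised tag
UNIT_FACTORS: dict[str, float] = {
    # concentrations -> molar
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12,
    # time -> seconds
    "s": 1.0, "min": 60.0, "ms": 1e-3,
    # volumes -> liters
    "l": 1.0, "ml": 1e-3, "ul": 1e-6,
    # passthrough units kept at their natural scale
    "C": 1.0, "nm": 1.0, "kcal_per_mol": 1.0, "au": 1.0,
}

_UNITLESS = {"", None}


def split_unit_tag(column: str) -> tuple[str, str | None]:
    """Split ``conc_uM`` into ('conc', 'uM'); unknown suffixes return None.

    Longest matching tag wins so composite tags like ``kcal_per_mol`` are
    recognised.
    """
    for tag in sorted(UNIT_FACTORS, key=len, reverse=True):
        if column.endswith("_" + tag):
            return column[: -len(tag) - 1], tag
    return column, None


def read_table(path: str | Path, required: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a unit-tagged CSV and normalise tagged columns to internal units.

    ``required`` maps output column names to the physical quantity expected,
    e.g. ``{"conc": "concentration"}``; a required column whose header
    carries no recognised unit tag raises, listing the accepted tags.
    Untagged non-required columns pass through unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    out = {}
    tags = {}
    for col in df.columns:
        stem, tag = split_unit_tag(col)
        if tag is not None and pd.api.types.is_numeric_dtype(df[col]):
            out[stem] = df[col].to_numpy(dtype=float) * UNIT_FACTORS[tag]
            tags[stem] = tag
        else:
            out[stem] = df[col].to_numpy()
    result = pd.DataFrame(out)
    result.attrs["unit_tags"] = tags
    result.attrs["source"] = str(path)
    if required:
        for name, quantity in required.items():
            if name not in result.columns:
                raise ValueError(
                    f"{path}: missing {quantity} column {name!r}; unit-tagged "
                    f"headers accepted: {name}_<tag> with tag in "
                    f"{sorted(UNIT_FACTORS)}"
                )
            if name not in tags and quantity not in ("label", "dimensionless"):
                raise ValueError(
                    f"{path}: column for {quantity} must carry a unit tag "
                    f"({name}_<tag>, tag in {sorted(UNIT_FACTORS)})"
                )
    return result


def write_table(df: pd.DataFrame, path: str | Path,
                units: dict[str, str] | None = None) -> Path:
    """Write a table with unit-tagged headers, converting from internal units."""
    path = Path(path)
    units = units or {}
    out = {}
    for col in df.columns:
        if col in units:
            tag = units[col]
            if tag not in UNIT_FACTORS:
                raise ValueError(f"unknown unit tag {tag!r}")
            out[f"{col}_{tag}"] = np.asarray(df[col], dtype=float) / UNIT_FACTORS[tag]
        else:
            out[col] = df[col].to_numpy()
    pd.DataFrame(out).to_csv(path, index=False)
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ResultReport:
    """Fit outcome plus provenance, losslessly (de)serializable to JSON."""

    assay: str
    parameters: dict[str, dict]  # name -> {value, stderr, unit}
    diagnostics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    schema_version: str = REPORT_SCHEMA_VERSION

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema_version": self.schema_version,
            "assay": self.assay,
            "parameters": self.parameters,
            "diagnostics": self.diagnostics,
            "provenance": self.provenance,
        }
        text = json.dumps(_clean(payload), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ResultReport":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            assay=d["assay"], parameters=d["parameters"],
            diagnostics=d.get("diagnostics", {}),
            provenance=d.get("provenance", {}),
            schema_version=d.get("schema_version", REPORT_SCHEMA_VERSION),
        )


def _clean(obj):
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return _clean(obj.item())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj
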