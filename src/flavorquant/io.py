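"""Delimited-text readers and writers for peak tables and batch manifests.

Peak tables: CSV with header ``sample_id,analyte,area,rt,fwhm,mz``
(fwhm and mz optional, empty allowed), one row per (injection, species);
internal-standard peaks appear as ordinary rows under the IS name.

Manifests: CSV with header ``sample_id,role,batch_id,injection_order,
flavor_category,dilution_factor,aliquot_volume_ul,is_volume_ul,
solvent_volume_ul,nominal``; ``nominal`` encodes the per-analyte spike map
as ``Name=conc;Name=conc`` (empty for commercial liquids and blanks).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ConfigError

PEAK_COLUMNS = ["sample_id", "analyte", "area", "rt", "fwhm", "mz"]
MANIFEST_COLUMNS = [
    "sample_id",
    "role",
    "batch_id",
    "injection_order",
    "flavor_category",
    "dilution_factor",
    "aliquot_volume_ul",
    "is_volume_ul",
    "solvent_volume_ul",
    "nominal",
]

ROLES = {
    "calibrator",
    "qc",
    "fortified",
    "lloq_fortified",
    "blank_pgvg",
    "blank_methanol",
    "commercial",
    "dilution_check",
    "stability",
}


def encode_nominal(nominal: dict[str, float]) -> str:
    return ";".join(f"{k}={v:g}" for k, v in nominal.items())


def decode_nominal(text: str | float | None) -> dict[str, float]:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return {}
    out: dict[str, float] = {}
    for chunk in str(text).split(";"):
        name, _, value = chunk.partition("=")
        out[name] = float(value)
    return out


def read_peak_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"peak table not found: {path}")
    df = pd.read_csv(path, dtype={"sample_id": str, "analyte": str})
    missing = set(PEAK_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ConfigError(f"peak table {path} is missing columns {sorted(missing)}")
    for col in ("fwhm", "mz"):
        if col not in df.columns:
            df[col] = pd.NA
    if df["area"].isna().any():
        bad = df.index[df["area"].isna()][0]
        raise ConfigError(f"peak table {path}: missing area at row {bad + 2}")
    return df[PEAK_COLUMNS]


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=PEAK_COLUMNS, float_format="%.6g")


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"sample_id": str, "batch_id": str, "role": str})
    missing = {"sample_id", "role", "batch_id", "injection_order"} - set(df.columns)
    if missing:
        raise ConfigError(f"manifest {path} is missing columns {sorted(missing)}")
    bad_roles = set(df["role"]) - ROLES
    if bad_roles:
        raise ConfigError(f"manifest {path} has unknown roles {sorted(bad_roles)}")
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df["dilution_factor"] = df["dilution_factor"].fillna(1.0).astype(float)
    dup = df.duplicated(subset=["batch_id", "injection_order"])
    if dup.any():
        raise ConfigError(f"manifest {path}: duplicate injection order within a batch")
    return df[MANIFEST_COLUMNS]


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=MANIFEST_COLUMNS)
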