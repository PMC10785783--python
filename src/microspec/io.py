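"""CSV dialects and packaged reference data.

Two plain-text dialects are used throughout (UTF-8, comma-separated,
"." decimal separator, mandatory header row):

* constants table — ``compound_id, method, role, model_type, parent_id,
  log_K1, se_K1, log_K2, se_K2``; parent rows are symmetric diprotics,
  model rows monoprotic derivatives (``log_K2`` empty).
* titration table — ``compound_id, flavor, pH, signal, nucleus_label,
  replicate_id``; metadata (concentrations, volumes, temperature, ionic
  strength) travels in a sidecar YAML/JSON file.

``packaged_constants_table`` returns the bundled reference table of
experimentally determined protonation constants for eleven symmetric
diprotic parents (dicarboxylic acids, diphenols, dithiols) and their
O-methyl / amide / S-methyl model derivatives, by NMR and potentiometric
titration.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .titration import TitrationDataset

_CONSTANT_COLS = [
    "compound_id",
    "method",
    "role",
    "model_type",
    "parent_id",
    "log_K1",
    "se_K1",
    "log_K2",
    "se_K2",
]


def load_constants_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a constants-table CSV and validate its columns."""
    df = pd.read_csv(path, dtype={"compound_id": str, "parent_id": str})
    missing = set(_CONSTANT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"constants table missing columns: {sorted(missing)}")
    df["model_type"] = df["model_type"].fillna("")
    df["parent_id"] = df["parent_id"].fillna("")
    return df


def packaged_constants_table() -> pd.DataFrame:
    """The bundled reference protonation-constants table."""
    ref = resources.files("microspec.data").joinpath(
        "protonation_constants.csv"
    )
    with resources.as_file(ref) as path:
        return load_constants_table(path)


def load_titration_csv(
    path: Union[str, Path],
    metadata: Optional[Union[str, Path, dict]] = None,
) -> dict[tuple[str, str], TitrationDataset]:
    """Read a titration CSV into datasets keyed by (compound_id, flavor).

    ``metadata`` may be a dict or a path to a YAML/JSON sidecar; it is
    attached to every dataset.  Non-numeric pH or signal cells raise a
    row-level error naming the offending line.
    """
    df = pd.read_csv(path)
    required = {"compound_id", "flavor", "pH", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"titration CSV missing columns: {sorted(missing)}")
    for col in ("pH", "signal"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line and 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path}: non-numeric {col} value "
                f"{df.loc[bad.idxmax(), col]!r} on line {line}"
            )
        df[col] = coerced
    if df[["pH", "signal"]].isna().any().any():
        line = int(df[["pH", "signal"]].isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"{path}: missing pH/signal value on line {line}")

    meta: dict = {}
    if isinstance(metadata, dict):
        meta = dict(metadata)
    elif metadata is not None:
        text = Path(metadata).read_text()
        meta = (
            json.loads(text)
            if str(metadata).endswith(".json")
            else yaml.safe_load(text)
        ) or {}

    out: dict[tuple[str, str], TitrationDataset] = {}
    for (cid, flavor), grp in df.groupby(["compound_id", "flavor"]):
        pts = pd.DataFrame({"pH": grp["pH"], "signal": grp["signal"]})
        if "nucleus_label" in grp.columns and grp["nucleus_label"].notna().any():
            pts["nucleus"] = grp["nucleus_label"]
        if "replicate_id" in grp.columns and grp["replicate_id"].notna().any():
            pts["replicate"] = grp["replicate_id"]
        out[(cid, flavor)] = TitrationDataset(
            compound_id=cid,
            flavor=flavor,
            points=pts.reset_index(drop=True),
            metadata=dict(meta),
        )
    return out


def write_titration_csv(
    datasets, path: Union[str, Path]
) -> None:
    """Write one or more datasets to the titration CSV dialect."""
    if isinstance(datasets, TitrationDataset):
        datasets = [datasets]
    elif isinstance(datasets, dict):
        datasets = list(datasets.values())
    frames = []
    for ds in datasets:
        df = ds.points.copy()
        df.insert(0, "compound_id", ds.compound_id)
        df.insert(1, "flavor", ds.flavor)
        df = df.rename(
            columns={"nucleus": "nucleus_label", "replicate": "replicate_id"}
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_macro_csv(results, path: Union[str, Path]) -> None:
    """Write fitted macroconstants (one row per compound/method)."""
    rows = []
    for res in results:
        macro = res.macro
        row = {"compound_id": macro.compound_id, "method": macro.method}
        for i, (lk, se) in enumerate(zip(macro.log_K, macro.se_log_K), 1):
            row[f"log_K{i}"] = lk
            row[f"se_K{i}"] = se
        row["residual_sd"] = res.residual_sd
        row["converged"] = res.converged
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
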