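"""File formats: trace CSV, plate layout CSV, library CSV/FASTA, results TSV.

All files are plain text with fixed schemas.  Concentration columns always
carry an explicit unit column; internal storage is molar.  Result files
start with ``#`` provenance comment lines (package version, seed, config
hash) which every reader skips, so all outputs round-trip through the
package.  Writes go to a temporary file first and are renamed into place,
so a failed run never leaves a partial file.
"""

from __future__ import annotations

import hashlib
import json
import os
import re
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .library import PeptideLibrary
from .traces import TricTrace
from .units import from_molar, to_molar

__all__ = [
    "FormatError",
    "read_traces",
    "write_traces",
    "read_layout",
    "write_layout",
    "read_library",
    "write_library",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
]

_WELL_RE = re.compile(r"^[A-P](0?[1-9]|1[0-9]|2[0-4])$")


class FormatError(ValueError):
    """Malformed input file; message cites the offending rows."""


def provenance(seed: "int | None" = None, config_text: "str | None" = None) -> dict:
    meta = {"package": f"tricscreen {__version__}"}
    if seed is not None:
        meta["seed"] = seed
    if config_text is not None:
        meta["config_sha256"] = hashlib.sha256(config_text.encode()).hexdigest()[:16]
    return meta


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _header(meta: "dict | None") -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path, *, sep: str = "\t", meta: "dict | None" = None) -> None:
    """Write a results table with provenance comment header (TSV default)."""
    _atomic_write(path, _header(meta) + df.to_csv(sep=sep, index=False))


def read_table(path, *, sep: "str | None" = None) -> pd.DataFrame:
    sep = sep if sep is not None else ("\t" if str(path).endswith(".tsv") else ",")
    return pd.read_csv(path, sep=sep, comment="#")


def write_json(obj, path, *, meta: "dict | None" = None) -> None:
    payload = {"_provenance": meta, **obj} if meta else obj
    _atomic_write(path, json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_traces(traces: "list[TricTrace]", path, *, meta: "dict | None" = None) -> None:
    """Long-format trace CSV: plate_id,well_id,time_s,fluorescence."""
    frames = [
        pd.DataFrame(
            {
                "plate_id": t.plate_id,
                "well_id": t.well_id,
                "time_s": t.time,
                "fluorescence": t.fluorescence,
            }
        )
        for t in traces
    ]
    df = pd.concat(frames, ignore_index=True)
    _atomic_write(path, _header(meta) + df.to_csv(index=False))


def read_traces(path) -> "list[TricTrace]":
    """Read and validate a long-format trace CSV into grouped traces.

    Rejects non-numeric or missing values (citing 1-based data row numbers)
    and non-monotone time within a well.
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    required = {"well_id", "time_s", "fluorescence"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    if "plate_id" not in df.columns:
        df["plate_id"] = "plate1"
    for col in ("time_s", "fluorescence"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | ~np.isfinite(vals)]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
            raise FormatError(f"{path}: non-numeric/missing {col} at line(s) {rows}")
        df[col] = vals
    traces = []
    for (plate, well), grp in df.groupby(["plate_id", "well_id"], sort=False):
        t = grp["time_s"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise FormatError(f"{path}: non-monotone time in well {plate}:{well}")
        traces.append(
            TricTrace(
                well_id=well, time=t, fluorescence=grp["fluorescence"].to_numpy(),
                plate_id=plate,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# plate layout
# ---------------------------------------------------------------------------

def write_layout(
    layout: pd.DataFrame, path, *, unit: str = "uM", meta: "dict | None" = None
) -> None:
    """Plate-layout CSV with explicit concentration unit column."""
    out = layout.copy()
    out["concentration"] = [from_molar(v, unit) for v in out.pop("concentration_m")]
    out["concentration_unit"] = unit
    _atomic_write(path, _header(meta) + out.to_csv(index=False))


def read_layout(path) -> pd.DataFrame:
    """Read and validate a plate-layout CSV (concentrations to molar)."""
    df = pd.read_csv(path, comment="#")
    required = {"plate_id", "well_id", "peptide_id", "role", "concentration", "concentration_unit"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    bad_wells = [w for w in df["well_id"] if not _WELL_RE.match(str(w))]
    if bad_wells:
        raise FormatError(f"{path}: invalid 384-well ids {bad_wells[:5]}")
    dup = df.duplicated(subset=["plate_id", "well_id"])
    if dup.any():
        pairs = df.loc[dup, ["plate_id", "well_id"]].iloc[0].tolist()
        raise FormatError(f"{path}: duplicate (plate, well) {pairs}")
    bad_roles = set(df["role"]) - {"test", "control", "reference"}
    if bad_roles:
        raise FormatError(f"{path}: unknown roles {sorted(bad_roles)}")
    for plate, grp in df.groupby("plate_id"):
        if (grp["role"] == "test").any() and not (grp["role"] == "control").any():
            raise FormatError(f"{path}: plate {plate} has test wells but no control well")
    df["concentration_m"] = [
        to_molar(v, u) for v, u in zip(df["concentration"], df["concentration_unit"])
    ]
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return df.drop(columns=["concentration", "concentration_unit"])


# ---------------------------------------------------------------------------
# peptide libraries
# ---------------------------------------------------------------------------

def write_library(library: PeptideLibrary, path, *, meta: "dict | None" = None) -> None:
    """Library CSV; parent metadata goes into the comment header."""
    head = dict(meta or {})
    head.update(
        parent_id=library.parent_id,
        parent_sequence=library.parent_sequence,
        parent_start=library.parent_start,
    )
    _atomic_write(path, _header(head) + library.entries.to_csv(index=False))


def read_library(path) -> PeptideLibrary:
    """Read a library from CSV (full metadata) or FASTA (sequences only).

    CSV entries are re-validated against the parent recorded in the header;
    inconsistent windows or substitutions are rejected citing the peptide.
    Lowercase FASTA sequences are accepted and uppercased.
    """
    path = str(path)
    if path.endswith((".fasta", ".fa", ".faa")):
        rows = []
        for rec in SeqIO.parse(path, "fasta"):
            rows.append(
                {
                    "peptide_id": rec.id,
                    "sequence": str(rec.seq).upper(),
                    "parent_id": "",
                    "start": 1,
                    "end": len(rec.seq),
                    "sub_pos": np.nan,
                    "sub_res": "",
                    "is_wt": False,
                }
            )
        if not rows:
            raise FormatError(f"{path}: no FASTA records")
        return PeptideLibrary(pd.DataFrame(rows))
    head = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            head[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#", keep_default_na=False,
                     na_values={"sub_pos": [""]})
    df["sub_pos"] = pd.to_numeric(df["sub_pos"], errors="coerce")
    df["is_wt"] = df["is_wt"].astype(str).str.lower().isin({"true", "1"})
    return PeptideLibrary(
        df,
        parent_id=head.get("parent_id", ""),
        parent_sequence=head.get("parent_sequence", ""),
        parent_start=int(head.get("parent_start", 1)),
    )
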