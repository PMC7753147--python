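"""Peptide library design, microarray normalization and array/TRIC comparison.

Overlapping (tiling) libraries locate binding sites along a parent protein
region; positional-scan libraries substitute every residue of a parent
peptide by every amino acid to map per-position binding requirements.
Residue coordinates are 1-based inclusive throughout, matching the
superscript numbering convention used for receptor-loop peptides
(e.g. FSIVG at positions 420-424 of the GlyR beta subunit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .binding import BinarySystem, solve_binary

__all__ = [
    "AMINO_ACIDS",
    "PeptideLibrary",
    "PositionalScanMatrix",
    "ArrayTricComparison",
    "make_overlapping_library",
    "make_positional_scan",
    "simulate_array",
    "normalize_to_wt",
    "correlate_array_tric",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

_COLUMNS = ["peptide_id", "sequence", "parent_id", "start", "end", "sub_pos", "sub_res", "is_wt"]


def _check_sequence(seq: str, context: str) -> str:
    seq = str(seq)
    bad = set(seq) - _AA_SET
    if bad:
        raise ValueError(f"{context}: invalid residue codes {sorted(bad)} in {seq!r}")
    return seq


@dataclass(frozen=True)
class PeptideLibrary:
    """A table of peptides with parent coordinates and substitution metadata.

    Columns: peptide_id, sequence, parent_id, start, end (1-based inclusive
    coordinates in the parent numbering), sub_pos, sub_res (position and
    residue of a point substitution; NaN/empty for unmutated windows) and
    is_wt (entry identical to the parent window).
    """

    entries: pd.DataFrame
    parent_id: str = ""
    parent_sequence: str = ""
    parent_start: int = 1

    def __post_init__(self) -> None:
        df = self.entries
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"library table missing columns {missing}")
        if df["peptide_id"].duplicated().any():
            dup = df.loc[df["peptide_id"].duplicated(), "peptide_id"].iloc[0]
            raise ValueError(f"duplicate peptide_id {dup!r}")
        for _, row in df.iterrows():
            _check_sequence(row["sequence"], row["peptide_id"])
            if self.parent_sequence:
                sub = self.window_sequence(int(row["start"]), int(row["end"]))
                expect = sub
                if not pd.isna(row["sub_pos"]):
                    pos = int(row["sub_pos"]) - int(row["start"])
                    expect = sub[:pos] + str(row["sub_res"]) + sub[pos + 1:]
                if row["sequence"] != expect:
                    raise ValueError(
                        f"{row['peptide_id']}: sequence {row['sequence']} inconsistent "
                        f"with parent window {row['start']}-{row['end']}"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def window_sequence(self, start: int, end: int) -> str:
        i = start - self.parent_start
        return self.parent_sequence[i : i + (end - start + 1)]

    def ki_map(self, default: float = float("nan")) -> dict:
        return {pid: default for pid in self.entries["peptide_id"]}


def make_overlapping_library(
    parent_sequence: str,
    *,
    parent_id: str = "parent",
    length: int = 15,
    offset: int = 1,
    parent_start: int = 1,
) -> PeptideLibrary:
    """Tiling peptide windows of fixed length stepped along a parent.

    ``parent_start`` anchors the 1-based numbering (e.g. 378 for a receptor
    loop construct whose first residue is residue 378 of the full protein).
    """
    parent_sequence = _check_sequence(parent_sequence.upper(), parent_id)
    n = len(parent_sequence)
    if n < length:
        raise ValueError(f"parent length {n} shorter than window length {length}")
    rows = []
    for i in range(0, n - length + 1, offset):
        start = parent_start + i
        end = start + length - 1
        rows.append(
            {
                "peptide_id": f"{parent_id}_{start}_{end}",
                "sequence": parent_sequence[i : i + length],
                "parent_id": parent_id,
                "start": start,
                "end": end,
                "sub_pos": np.nan,
                "sub_res": "",
                "is_wt": True,
            }
        )
    return PeptideLibrary(pd.DataFrame(rows), parent_id, parent_sequence, parent_start)


def make_positional_scan(
    parent_sequence: str,
    *,
    parent_id: str = "parent",
    positions: "range | list | None" = None,
    alphabet: str = AMINO_ACIDS,
    parent_start: int = 1,
) -> PeptideLibrary:
    """Full positional-scan library of a parent peptide.

    One variant per (position, residue) pair over the requested positions
    (all of the parent by default), including the WT-identical entries,
    which are marked ``is_wt``.  Positions are in the parent's 1-based
    numbering.
    """
    parent_sequence = _check_sequence(parent_sequence.upper(), parent_id)
    for a in alphabet:
        if a not in _AA_SET:
            raise ValueError(f"invalid residue code {a!r} in alphabet")
    n = len(parent_sequence)
    end_full = parent_start + n - 1
    if positions is None:
        positions = range(parent_start, end_full + 1)
    rows = []
    for pos in positions:
        i = pos - parent_start
        if not 0 <= i < n:
            raise ValueError(f"position {pos} outside parent {parent_start}-{end_full}")
        for res in alphabet:
            seq = parent_sequence[:i] + res + parent_sequence[i + 1 :]
            is_wt = res == parent_sequence[i]
            rows.append(
                {
                    "peptide_id": f"{parent_id}_{pos}{res}",
                    "sequence": seq,
                    "parent_id": parent_id,
                    "start": parent_start,
                    "end": end_full,
                    "sub_pos": pos,
                    "sub_res": res,
                    "is_wt": is_wt,
                }
            )
    return PeptideLibrary(pd.DataFrame(rows), parent_id, parent_sequence, parent_start)


# ---------------------------------------------------------------------------
# synthetic microarray data
# ---------------------------------------------------------------------------

def simulate_array(
    library: PeptideLibrary,
    ki_map: dict,
    *,
    probe_concentration: float = 50e-9,
    n_arrays: int = 3,
    noise_cv: float = 0.05,
    intensity_scale: float = 1e4,
    background: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic spot-intensity table for replicate arrays.

    Spot intensity is proportional to the equilibrium occupancy of the
    immobilized peptide by the probe protein at the probing concentration
    (Langmuir isotherm on each variant's true affinity), times the capture
    capacity ``intensity_scale``, with multiplicative log-normal-like
    Gaussian noise per spot.  Non-binders (NaN/None K_i) produce
    background-level spots.  Returns a long table
    (array_id, peptide_id, role, intensity).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(1, n_arrays + 1):
        aid = f"array{a}"
        for pid in library.entries["peptide_id"]:
            ki = ki_map.get(pid)
            ki = float("nan") if ki is None else float(ki)
            if np.isfinite(ki):
                occ = solve_binary(
                    BinarySystem(
                        receptor_total=probe_concentration,
                        tracer_total=probe_concentration * 1e-6,  # spot amount << probe
                        kd_tracer=ki,
                    )
                ).tracer_bound_fraction
            else:
                occ = 0.0
            signal = intensity_scale * occ + background
            if noise_cv > 0:
                signal *= 1.0 + noise_cv * rng.standard_normal()
            rows.append(
                {"array_id": aid, "peptide_id": pid, "role": "spot",
                 "intensity": max(signal, 0.0)}
            )
        rows.append(
            {"array_id": aid, "peptide_id": "NEG", "role": "neg_control",
             "intensity": max(background * (1.0 + noise_cv * rng.standard_normal()), 0.0)}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PositionalScanMatrix:
    """Positions x residues grid of WT-normalized binding intensities."""

    parent_id: str
    grid: pd.DataFrame  # index: position, columns: residues, values: mean rel. intensity
    sd: pd.DataFrame
    n: pd.DataFrame
    records: pd.DataFrame  # tidy per-variant table (peptide_id, position, residue, ...)


def normalize_to_wt(
    spots: pd.DataFrame,
    library: PeptideLibrary,
    *,
    wt_ids: "list | None" = None,
    subtract_background: bool = True,
) -> PositionalScanMatrix:
    """WT-normalized positional-scan matrix from replicate array intensities.

    Per array: optionally subtract that array's negative-control mean
    (floored at zero), then divide by the array's mean WT-spot intensity;
    cell means and SDs are then taken across arrays.  Arrays lacking a WT
    spot are excluded with a warning-level note in the output records.
    """
    lib = library.entries.set_index("peptide_id")
    if wt_ids is None:
        wt_ids = list(lib.index[lib["is_wt"]])
    if not wt_ids:
        raise ValueError("no WT entries to normalize against")
    per_array = []
    for aid, sub in spots.groupby("array_id"):
        spot = sub[sub["role"] == "spot"].copy()
        if subtract_background:
            neg = sub.loc[sub["role"] == "neg_control", "intensity"]
            bg = float(neg.mean()) if len(neg) else 0.0
            spot["intensity"] = np.maximum(spot["intensity"] - bg, 0.0)
        wt = spot.loc[spot["peptide_id"].isin(wt_ids), "intensity"]
        if len(wt) == 0 or wt.mean() <= 0:
            continue  # array unusable: no WT normalizer
        spot["rel_intensity"] = spot["intensity"] / wt.mean()
        spot["array_id"] = aid
        per_array.append(spot[["array_id", "peptide_id", "rel_intensity"]])
    if not per_array:
        raise ValueError("no array with a usable WT normalizer")
    rel = pd.concat(per_array)
    agg = rel.groupby("peptide_id")["rel_intensity"].agg(["mean", "std", "count"])
    records = agg.join(lib[["sub_pos", "sub_res", "is_wt"]], how="inner").reset_index()
    records = records.rename(
        columns={"mean": "rel_intensity", "std": "rel_intensity_sd", "count": "n"}
    )
    scan = records.dropna(subset=["sub_pos"]).copy()
    scan["sub_pos"] = scan["sub_pos"].astype(int)
    grid = scan.pivot_table(index="sub_pos", columns="sub_res", values="rel_intensity")
    sd = scan.pivot_table(index="sub_pos", columns="sub_res", values="rel_intensity_sd")
    n = scan.pivot_table(index="sub_pos", columns="sub_res", values="n")
    return PositionalScanMatrix(
        parent_id=library.parent_id, grid=grid, sd=sd, n=n, records=records
    )


@dataclass(frozen=True)
class ArrayTricComparison:
    """Rank correlation between array intensity and in-solution affinity."""

    coefficient: float
    n_pairs: int
    censoring_policy: str
    pairs: pd.DataFrame  # peptide_id, rel_intensity, ki_m, censored


def correlate_array_tric(
    matrix: PositionalScanMatrix,
    fits,
    *,
    policy: str = "censored_lowest",
) -> ArrayTricComparison:
    """Spearman rank correlation of array intensity vs -log10 K_i.

    ``fits`` is a list of dose-response fits (or a mapping peptide_id ->
    K_i in molar, NaN meaning censored/non-binding).  Censored values are
    either ranked jointly below every finite affinity
    (``policy='censored_lowest'``, preserving order information without
    inventing affinities) or dropped (``policy='exclude'``).
    """
    from .doseresponse import DoseResponseFit  # local to avoid cycle at import

    ki_map = {}
    for f in (fits.items() if isinstance(fits, dict) else [(f.peptide_id, f) for f in fits]):
        pid, v = f
        if isinstance(v, DoseResponseFit):
            ki_map[pid] = float(v.ki) if np.isfinite(v.ki) else float("nan")
        else:
            ki_map[pid] = float("nan") if v is None else float(v)

    rec = matrix.records.set_index("peptide_id")
    rows = []
    for pid, ki in ki_map.items():
        if pid not in rec.index:
            continue
        rows.append(
            {
                "peptide_id": pid,
                "rel_intensity": float(rec.loc[pid, "rel_intensity"]),
                "ki_m": ki,
                "censored": not np.isfinite(ki),
            }
        )
    pairs = pd.DataFrame(rows)
    if policy == "exclude":
        pairs = pairs[~pairs["censored"]].reset_index(drop=True)
    elif policy != "censored_lowest":
        raise ValueError(f"unknown censoring policy {policy!r}")
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 paired records, have {len(pairs)}")

    x = pairs["rel_intensity"].to_numpy()
    neglog = np.where(
        pairs["censored"], -np.inf, -np.log10(np.where(pairs["censored"], 1.0, pairs["ki_m"]))
    )
    # average ranks; censored entries tie at the bottom (-inf)
    rx, ry = rankdata(x), rankdata(neglog)
    coef = float(np.corrcoef(rx, ry)[0, 1])
    return ArrayTricComparison(
        coefficient=coef, n_pairs=int(len(pairs)), censoring_policy=policy, pairs=pairs
    )
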