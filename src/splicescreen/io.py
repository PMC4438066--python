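"""Readers and writers for the pipeline's table formats.

All tables are UTF-8 text with headers, "NA" for missing values, "." as the
decimal separator, and PSI written as percent with one decimal.  The
supplementary-table reader understands the cross-evolutionary workbook
layout (columns a-am: assay definitions, mouse three-tissue PSI, human
six-tissue PSI, stem-cell differentiation PSI, zebrafish product sizes) in
.xlsx or CSV/TSV form.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservationCall, OrthologGroup
from .dynamics import DynamicsResult, TimeCourse
from .quant import QuantResult
from .screen import PsiMatrix, SwitchCall

__all__ = [
    "read_assays", "write_assays",
    "read_peaks", "write_peaks",
    "read_psi_matrix", "write_psi_matrix",
    "write_quant", "read_quant", "quant_to_psi_matrix",
    "write_screen", "read_screen", "calls_from_frame",
    "read_orthologs", "write_orthologs",
    "write_conserved", "write_funnel",
    "read_timecourses", "write_dynamics",
    "read_supplementary_table",
]

NA = "NA"


def _fmt(v, decimals: int = 1) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return NA
    return f"{v:.{decimals}f}"


# ---------------------------------------------------------------- flat tables

def read_assays(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    required = {"ase_id", "gene", "species", "event_type",
                "size_short_nt", "size_long_nt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    return df


def write_assays(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_peaks(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA], keep_default_na=False)
    required = {"ase_id", "sample_id", "size_nt", "conc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return df


def write_peaks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep=NA)


def read_orthologs(path) -> list[OrthologGroup]:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    groups = []
    for gid, sub in df.groupby("group_id", sort=True):
        members = dict(zip(sub["species"], sub["ase_id"]))
        if len(members) != len(sub):
            raise ValueError(f"group {gid!r}: more than one member per species")
        groups.append(OrthologGroup(str(gid), members))
    return groups


def write_orthologs(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


# ---------------------------------------------------------------- PSI matrix

def write_psi_matrix(matrix: PsiMatrix, path) -> None:
    """ASE x sample TSV, percent with one decimal, NA for missing/QC-failed.

    Cells that failed QC are written as NA: the written table carries
    exactly the values a downstream screen may use.
    """
    masked = matrix.values.where(matrix.qc)
    out = masked.map(lambda v: _fmt(v, 1))
    out.index.name = "ase_id"
    out.to_csv(path, sep="\t")


def read_psi_matrix(path) -> PsiMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA],
                     keep_default_na=False)
    return PsiMatrix(df.astype(float))


def quant_to_psi_matrix(results: Iterable[QuantResult], samples: Sequence[str]) -> PsiMatrix:
    """Pivot per-lane quantification into a PSI matrix with QC flags."""
    rows: dict[str, dict[str, float]] = {}
    qc: dict[str, dict[str, bool]] = {}
    for r in results:
        rows.setdefault(r.ase_id, {})[r.sample_id] = (
            np.nan if r.psi is None else r.psi
        )
        qc.setdefault(r.ase_id, {})[r.sample_id] = r.qc_pass
    values = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(samples))
    flags = (
        pd.DataFrame.from_dict(qc, orient="index")
        .reindex(columns=list(samples))
        .fillna(False)
        .astype(bool)
    )
    values = values.sort_index()
    return PsiMatrix(values, flags.loc[values.index])


# ------------------------------------------------------------- quant results

def write_quant(results: Iterable[QuantResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("ase_id\tsample_id\tmolarity_long\tmolarity_short\tpurity\tpsi\tqc_pass\n")
        for r in results:
            fh.write(
                f"{r.ase_id}\t{r.sample_id}\t{r.molarity_long:.6g}\t"
                f"{r.molarity_short:.6g}\t{_fmt(r.purity, 4)}\t"
                f"{_fmt(r.psi, 1)}\t{str(r.qc_pass).lower()}\n"
            )


def read_quant(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


# -------------------------------------------------------------- screen calls

def write_screen(calls: Iterable[SwitchCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("ase_id\treference\tshift\tdirection\tis_switch\tcomplete\n")
        for c in calls:
            fh.write(
                f"{c.ase_id}\t{c.reference_sample}\t{_fmt(c.shift, 1)}\t"
                f"{c.direction}\t{str(c.is_switch).lower()}\t{str(c.complete).lower()}\n"
            )


def read_screen(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


def calls_from_frame(df: pd.DataFrame) -> dict[str, SwitchCall]:
    """Rebuild {ase_id -> SwitchCall} from a written screen table."""
    out = {}
    for _, row in df.iterrows():
        shift = None if pd.isna(row["shift"]) else float(row["shift"])
        out[row["ase_id"]] = SwitchCall(
            ase_id=row["ase_id"],
            reference_sample=row["reference"],
            shift=shift,
            direction=int(row["direction"]),
            is_switch=bool(row["is_switch"] is True or str(row["is_switch"]).lower() == "true"),
            complete=bool(row["complete"] is True or str(row["complete"]).lower() == "true"),
        )
    return out


# ------------------------------------------------- conservation and dynamics

def write_conserved(calls: Iterable[ConservationCall], path) -> None:
    def flag(v):
        return NA if v is None else str(v).lower()

    with open(path, "w") as fh:
        fh.write("group_id\tspecies_evaluated\tall_switch\tdirection_consistent\tis_conserved\n")
        for c in calls:
            fh.write(
                f"{c.group_id}\t{','.join(c.species_evaluated) or NA}\t"
                f"{flag(c.all_switch)}\t{flag(c.direction_consistent)}\t"
                f"{str(c.is_conserved).lower()}\n"
            )


def write_funnel(funnel: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(funnel, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_timecourses(path, time_unit: str = "days") -> list[TimeCourse]:
    """Time-course table: ase_id index, columns are numeric time labels."""
    if time_unit not in ("days", "hpf"):
        raise ValueError(f"unknown time unit {time_unit!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA],
                     keep_default_na=False)
    try:
        times = tuple(float(c) for c in df.columns)
    except ValueError as exc:
        raise ValueError(f"time-course columns must be numeric times: {exc}") from exc
    out = []
    for ase_id, row in df.iterrows():
        psi = tuple(None if pd.isna(v) else float(v) for v in row)
        out.append(TimeCourse(str(ase_id), times, psi))
    return out


def write_timecourses(courses: Iterable[TimeCourse], path) -> None:
    courses = list(courses)
    if not courses:
        raise ValueError("no time courses to write")
    times = courses[0].times
    with open(path, "w") as fh:
        fh.write("ase_id\t" + "\t".join(f"{t:g}" for t in times) + "\n")
        for tc in courses:
            if tc.times != times:
                raise ValueError("all time courses must share the same time grid")
            fh.write(tc.ase_id + "\t" + "\t".join(_fmt(v, 1) for v in tc.psi) + "\n")


def write_dynamics(results: Iterable[DynamicsResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("ase_id\tnet_shift\trange\tis_switch\tdirection\tpivot_start\tpivot_end\n")
        for r in results:
            fh.write(
                f"{r.ase_id}\t{r.net_shift:.1f}\t{r.range:.1f}\t"
                f"{str(r.is_switch).lower()}\t{r.direction}\t"
                f"{r.pivot_interval[0]:g}\t{r.pivot_interval[1]:g}\n"
            )


# ------------------------------------------------------- supplementary table

def _col_letters(n: int) -> list[str]:
    """Spreadsheet column letters a, b, ..., z, aa, ab, ..."""
    out = []
    for i in range(n):
        s, j = "", i
        while True:
            s = chr(ord("a") + j % 26) + s
            j = j // 26 - 1
            if j < 0:
                break
        out.append(s)
    return out

# Tab1 column positions (0-based) in the a-am layout.
_TAB1_COLS = {
    "human_ase": 0, "mouse_gene": 1, "mouse_ase": 2, "event_type": 3,
    "mouse_size_short": 10, "mouse_size_long": 11,        # k, l
    "mouse_psi": (13, 14, 15),                            # n-p: brain, kidney, liver
    "mouse_shift": 16,                                    # q
    "human_gene": 17,                                     # r
    "human_size_short": 21, "human_size_long": 22,        # v, w
    "human_psi": (24, 25, 26, 27, 28, 29),                # y-ad
    "stem_psi": (30, 31, 32, 33, 34),                     # ae-ai
}
_TAB1_MIN_COLS = 35
_HUMAN_TISSUES = ("brain", "kidney", "liver", "lung", "muscle", "heart")
_MOUSE_TISSUES = ("brain", "kidney", "liver")
_STEM_DAYS = (0.0, 2.0, 6.0, 10.0, 14.0)


def _load_sheet(path, tab: int) -> pd.DataFrame:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xls":
        raise ValueError(
            "legacy .xls workbooks are not supported; convert the sheet to "
            ".xlsx or export it as CSV/TSV with the same column order"
        )
    if suffix == ".xlsx":
        return pd.read_excel(path, sheet_name=tab, header=0, engine="openpyxl")
    sep = "\t" if suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, header=0, na_values=["NA", ""],
                       keep_default_na=True)


def _num(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def read_supplementary_table(
    path, tab: int = 0
) -> tuple[pd.DataFrame, dict[str, PsiMatrix], list[TimeCourse]]:
    """Parse a cross-evolutionary splicing workbook (Tab1, columns a-am).

    Columns are mapped by position: assay identity and event type (a-d),
    mouse product sizes (k, l) and brain/kidney/liver PSI (n-p), human
    product sizes (v, w) and six-tissue PSI (y-ad), and neural stem-cell PSI
    at days 0/2/6/10/14 of differentiation (ae-ai).  Blank cells become
    missing; PSI is read on the percent scale.

    Returns ``(assay table, {"mouse": PsiMatrix, "human": PsiMatrix},
    stem-cell time courses)``; rows blank across all five stem-cell columns
    are excluded from the time-course set.
    """
    df = _load_sheet(path, tab)
    if df.shape[1] < _TAB1_MIN_COLS:
        letters = _col_letters(_TAB1_MIN_COLS)
        first_missing = letters[df.shape[1]]
        raise ValueError(
            f"unrecognised layout: expected >= {_TAB1_MIN_COLS} columns (a-am); "
            f"first unmapped column is {first_missing!r}"
        )
    C = _TAB1_COLS
    assay_rows, mouse_psi, human_psi, courses = [], {}, {}, []
    for _, row in df.iterrows():
        vals = row.to_numpy()
        human_ase = vals[C["human_ase"]]
        if human_ase is None or (isinstance(human_ase, float) and np.isnan(human_ase)):
            continue
        human_ase = str(human_ase)
        assay_rows.append({
            "ase_id": human_ase,
            "gene": str(vals[C["human_gene"]]),
            "mouse_ase": str(vals[C["mouse_ase"]]),
            "event_type": str(vals[C["event_type"]]).strip().lower(),
            "mouse_size_short_nt": _num(vals[C["mouse_size_short"]]),
            "mouse_size_long_nt": _num(vals[C["mouse_size_long"]]),
            "human_size_short_nt": _num(vals[C["human_size_short"]]),
            "human_size_long_nt": _num(vals[C["human_size_long"]]),
        })
        mouse_psi[human_ase] = {
            t: _num(vals[i]) for t, i in zip(_MOUSE_TISSUES, C["mouse_psi"])
        }
        human_psi[human_ase] = {
            t: _num(vals[i]) for t, i in zip(_HUMAN_TISSUES, C["human_psi"])
        }
        stem = [_num(vals[i]) for i in C["stem_psi"]]
        if any(v is not None for v in stem):
            courses.append(TimeCourse(human_ase, _STEM_DAYS, tuple(stem)))
    matrices = {
        "mouse": PsiMatrix(pd.DataFrame.from_dict(mouse_psi, orient="index",
                                                  columns=list(_MOUSE_TISSUES)).astype(float)),
        "human": PsiMatrix(pd.DataFrame.from_dict(human_psi, orient="index",
                                                  columns=list(_HUMAN_TISSUES)).astype(float)),
    }
    return pd.DataFrame(assay_rows), matrices, courses
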