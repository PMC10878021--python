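"""Readers and writers for the pipeline's external formats.

Everything tabular is tab-delimited UTF-8 with a header row; missing values
are serialized as empty strings.  In memory:

* expression matrices are ``pandas.DataFrame`` (probes or genes x samples,
  float, NaN = missing);
* sample sheets are validated ``DataFrame`` with one row per array;
* probe maps are ``pandas.Series`` probe_id -> gene symbol;
* drug-response tables are ``pandas.Series`` indexed by
  (cell_line, agent) holding log10(GI50) in uM;
* gene-set collections are :class:`GeneSetCollection` (GMT dialect).

Identifiers are opaque, case-sensitive strings; no symbol aliasing is
attempted.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import PanelFormatError, ValidationError

logger = logging.getLogger(__name__)

ARMS = ("vehicle", "low", "high")
TREATED_ARMS = ("low", "high")
DEFAULT_TIMES_HR = (2, 6, 24)

SHEET_COLUMNS = ("sample_id", "cell_line", "agent", "arm", "time_hr")


# ---------------------------------------------------------------------------
# expression matrix

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probe- (or gene-) level log2 expression matrix.

    First column holds probe ids, the header row sample ids; empty cells
    become NaN.  Duplicate probe ids and ragged rows are hard errors.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return pd.DataFrame(dtype=float)
        samples = header[1:]
        probes: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise PanelFormatError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"found {len(row)}"
                )
            probe = row[0]
            if probe in seen:
                raise PanelFormatError(f"{path}: duplicate probe id {probe!r}")
            seen.add(probe)
            probes.append(probe)
            try:
                rows.append([float(v) if v != "" else np.nan for v in row[1:]])
            except ValueError as exc:
                raise PanelFormatError(f"{path}: line {lineno}: {exc}") from None
    return pd.DataFrame(rows, index=pd.Index(probes, name="probe_id"),
                        columns=samples, dtype=float)


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="", index_label=matrix.index.name
                  or "probe_id")


# ---------------------------------------------------------------------------
# sample sheet

def read_sample_sheet(path: str | Path,
                      times_hr: Sequence[int] = DEFAULT_TIMES_HR) -> pd.DataFrame:
    """Read and validate a sample sheet.

    Required columns: sample_id, cell_line, agent, arm, time_hr (an optional
    ``tissue`` label is carried through).  Every treated (low/high) sample
    must have a time-matched vehicle partner for the same cell line and
    agent.
    """
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                               "cell_line": str,
                                               "agent": str,
                                               "arm": str})
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing sample-sheet columns {missing}")
    if "tissue" not in sheet.columns:
        sheet["tissue"] = ""
    sheet["time_hr"] = sheet["time_hr"].astype(int)
    validate_sample_sheet(sheet, times_hr=times_hr)
    return sheet


def validate_sample_sheet(sheet: pd.DataFrame,
                          times_hr: Sequence[int] = DEFAULT_TIMES_HR) -> None:
    dup = sheet["sample_id"][sheet["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample ids: {sorted(set(dup))}")
    bad_arm = set(sheet["arm"]) - set(ARMS)
    if bad_arm:
        raise ValidationError(f"unknown arm labels: {sorted(bad_arm)}")
    bad_time = set(sheet["time_hr"]) - set(int(t) for t in times_hr)
    if bad_time:
        raise ValidationError(
            f"time_hr values {sorted(bad_time)} outside declared time points "
            f"{tuple(times_hr)}"
        )
    treated = sheet[sheet["arm"].isin(TREATED_ARMS)]
    vehicle_keys = set(map(tuple, sheet.loc[sheet["arm"] == "vehicle",
                                            ["cell_line", "agent", "time_hr"]]
                           .itertuples(index=False)))
    orphan = sorted(
        set(map(tuple, treated[["cell_line", "agent", "time_hr"]]
                .itertuples(index=False))) - vehicle_keys
    )
    if orphan:
        raise ValidationError(
            "treated samples without a time-matched vehicle partner: "
            f"{orphan}"
        )


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# probe map

def read_probe_map(path: str | Path) -> pd.Series:
    """Read a two-column probe_id -> gene symbol map (many probes per gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "gene"):
        if col not in df.columns:
            raise PanelFormatError(f"{path}: missing column {col!r}")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise PanelFormatError(
            f"{path}: probe mapped more than once: {sorted(set(dup))}"
        )
    if df["gene"].isna().any() or (df["gene"] == "").any():
        raise PanelFormatError(f"{path}: empty gene symbol in probe map")
    return pd.Series(df["gene"].to_numpy(), index=df["probe_id"], name="gene")


def write_probe_map(probe_map: pd.Series, path: str | Path) -> None:
    probe_map.rename_axis("probe_id").rename("gene").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# drug response

def read_drug_response(path: str | Path) -> pd.Series:
    """Read a long-format log10(GI50) table: cell_line, agent, log_gi50."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_line": str, "agent": str})
    for col in ("cell_line", "agent", "log_gi50"):
        if col not in df.columns:
            raise PanelFormatError(f"{path}: missing column {col!r}")
    try:
        values = df["log_gi50"].astype(float)
    except (TypeError, ValueError) as exc:
        raise PanelFormatError(f"{path}: non-numeric log_gi50 value ({exc})") from None
    keys = df[["cell_line", "agent"]]
    dup = keys[keys.duplicated()]
    if len(dup):
        raise PanelFormatError(
            f"{path}: duplicate (cell_line, agent) pairs: "
            f"{sorted(map(tuple, dup.itertuples(index=False)))}"
        )
    idx = pd.MultiIndex.from_frame(keys)
    return pd.Series(values.to_numpy(), index=idx, name="log_gi50")


def write_drug_response(response: pd.Series, path: str | Path) -> None:
    df = response.rename("log_gi50").rename_axis(["cell_line", "agent"]).reset_index()
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)

@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """Ordered, name-unique collection of gene sets."""

    def __init__(self, sets: Iterable[GeneSet] = ()) -> None:
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValidationError(f"duplicate gene-set name {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def names(self) -> list[str]:
        return list(self._sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member TAB member ...

    Duplicate members within a line are de-duplicated (order kept) with a
    logged warning; duplicate set names and short lines are errors.
    """
    path = Path(path)
    collection = GeneSetCollection()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelFormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            name, description, *members = fields
            members = [m for m in members if m != ""]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning("%s: line %d: set %r has duplicate members; "
                               "de-duplicated", path, lineno, name)
            try:
                collection.add(GeneSet(name, description, tuple(unique)))
            except ValidationError:
                raise PanelFormatError(
                    f"{path}: line {lineno}: duplicate set name {name!r}"
                ) from None
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join((s.name, s.description, *s.members)) + "\n")


# ---------------------------------------------------------------------------
# generic long tables

def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")
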