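"""Readers and writers for trial-structure tables and labeled matrices.

Three input dialects describe the same thing — which treatments each
study compared:

* **long**: one row per study arm, columns ``study`` and ``treatment``;
* **wide**: one row per study, treatment columns ``t1..tK`` with missing
  markers for absent arms (the layout used by NICE Decision Support Unit
  technical support documents);
* **edges**: one row per direct comparison, two label columns.

All readers return the same :class:`~nmaconnect.network.EvidenceNetwork`
for equivalent inputs.  Treatment codes are always read as strings, even
when they look numeric, so ordering and leading zeros survive.

Matrices are written as CSV/TSV with treatment labels as the first row
and first column; the blocked layout groups connected components into
diagonal blocks, with off-block cells carrying the chosen unconnected
code (blank cells reproduce the usual published presentation).
"""

from __future__ import annotations

import csv
import io as _io
import re
import warnings
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .matrices import (
    ComponentPartition,
    DistanceMatrix,
    IndirectConnectionMatrix,
    block_sort,
)
from .network import (
    EvidenceNetwork,
    InvalidNetworkError,
    StudyRecord,
    network_from_edges,
    network_from_studies,
)

#: Markers accepted as "no treatment in this arm slot" in the wide format.
MISSING_MARKERS = frozenset({"", "NA", "."})

_WIDE_COL = re.compile(r"^t\d+$", re.IGNORECASE)


class FormatError(ValueError):
    """Raised when an input table does not match the expected dialect."""


def _read_table(
    source: str | Path | IO[str],
    delimiter: str | None,
    header: bool = True,
) -> pd.DataFrame:
    """Read a delimited text table with all cells kept as stripped strings."""
    try:
        df = pd.read_csv(
            source,
            sep=delimiter,
            engine="python" if delimiter is None else "c",
            dtype=str,
            keep_default_na=False,
            header=0 if header else None,
            skip_blank_lines=True,
        )
    except (pd.errors.EmptyDataError, csv.Error):
        raise FormatError("input table is empty or undelimited") from None
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed input table: {exc}") from None
    df.columns = [str(c).strip() for c in df.columns]
    return df.apply(lambda col: col.str.strip())


def read_long_arm_table(
    source: str | Path | IO[str], delimiter: str | None = None
) -> EvidenceNetwork:
    """Arm-level long table: columns ``study`` and ``treatment``.

    One study record per distinct study id; the study's edges are all
    within-study treatment pairs.  A duplicated (study, treatment) row
    is collapsed with a warning.  Label order is first appearance.
    """
    df = _read_table(source, delimiter)
    cols = {c.lower(): c for c in df.columns}
    for required in ("study", "treatment"):
        if required not in cols:
            raise FormatError(
                f"long format needs a {required!r} column; found {list(df.columns)}"
            )
    study_col, trt_col = cols["study"], cols["treatment"]
    if (df[study_col] == "").any() or (df[trt_col] == "").any():
        raise FormatError("long format cells must be non-empty")
    studies: list[StudyRecord] = []
    for sid in df[study_col].unique():
        arms = list(df.loc[df[study_col] == sid, trt_col])
        if len(set(arms)) != len(arms):
            warnings.warn(
                f"study {sid!r} repeats a treatment row; duplicates collapsed"
            )
            arms = list(dict.fromkeys(arms))
        studies.append(StudyRecord(str(sid), tuple(arms)))
    return network_from_studies(studies)


def read_dsu_wide(
    source: str | Path | IO[str],
    delimiter: str | None = None,
    header: bool = True,
) -> EvidenceNetwork:
    """Wide treatment matrix: one row per study, columns ``t1..tK``.

    The non-missing entries of a row are the study's arms.  Accepted
    missing markers are ``NA``, ``.`` and the empty cell.  With
    ``header=False`` the columns are assumed to be ``t1..tK`` in order.
    Any columns not matching ``t<number>`` (for example study ids or
    outcome columns) are ignored.
    """
    df = _read_table(source, delimiter, header=header)
    if not header:
        df.columns = [f"t{i + 1}" for i in range(df.shape[1])]
    tcols = [c for c in df.columns if _WIDE_COL.match(c)]
    if not tcols:
        raise FormatError(
            f"wide format needs treatment columns t1..tK; found {list(df.columns)}"
        )
    tcols.sort(key=lambda c: int(c[1:]))
    studies: list[StudyRecord] = []
    for idx, row in df[tcols].iterrows():
        arms = [v for v in row if v.upper() not in MISSING_MARKERS and v != "."]
        if not arms:
            warnings.warn(f"row {idx} has no treatment arms; skipped")
            continue
        studies.append(StudyRecord(str(idx + 1), tuple(arms)))
    if not studies:
        raise FormatError("no usable study rows in wide-format input")
    return network_from_studies(studies)


def read_edge_list(
    source: str | Path | IO[str], delimiter: str | None = None
) -> EvidenceNetwork:
    """Plain edge list: two columns of treatment labels, one edge per row.

    Duplicate pairs collapse to one edge; a self-pair is an error (the
    message names the offending row).
    """
    df = _read_table(source, delimiter)
    if df.shape[1] != 2:
        raise FormatError(
            f"edge list needs exactly two columns; found {list(df.columns)}"
        )
    pairs: list[tuple[str, str]] = []
    for idx, (a, b) in enumerate(df.itertuples(index=False), start=1):
        if not a or not b:
            raise FormatError(f"edge row {idx} has an empty label")
        if a == b:
            raise InvalidNetworkError(
                f"edge row {idx} compares treatment {a!r} with itself"
            )
        pairs.append((a, b))
    return network_from_edges(pairs)


def read_network(
    source: str | Path | IO[str],
    fmt: str = "auto",
    delimiter: str | None = None,
) -> EvidenceNetwork:
    """Dispatch to the dialect reader; ``fmt='auto'`` sniffs the header."""
    if fmt == "long":
        return read_long_arm_table(source, delimiter)
    if fmt == "wide":
        return read_dsu_wide(source, delimiter)
    if fmt == "edges":
        return read_edge_list(source, delimiter)
    if fmt != "auto":
        raise FormatError(f"unknown input format {fmt!r}")
    text = Path(source).read_text() if isinstance(source, (str, Path)) else source.read()
    head = text.splitlines()[0] if text.strip() else ""
    cols = [c.strip().lower() for c in re.split(r"[,\t;]", head)]
    if "study" in cols and "treatment" in cols:
        return read_long_arm_table(_io.StringIO(text), delimiter)
    if any(_WIDE_COL.match(c) for c in cols):
        return read_dsu_wide(_io.StringIO(text), delimiter)
    if len(cols) == 2:
        return read_edge_list(_io.StringIO(text), delimiter)
    raise FormatError(
        "could not auto-detect input format; pass fmt='long'|'wide'|'edges'"
    )


# ---------------------------------------------------------------------------
# labeled matrix output
# ---------------------------------------------------------------------------

def _partition_from_matrix(
    matrix: IndirectConnectionMatrix | DistanceMatrix,
) -> ComponentPartition:
    """Recover the component partition from a connection/distance matrix.

    For both matrix types a nonzero off-diagonal entry marks a pair in
    the same component, so grouping rows by their nonzero pattern gives
    the components directly.
    """
    ent = matrix.entries
    n = len(matrix.labels)
    linked = (ent != 0) & (ent != -1)
    np.fill_diagonal(linked, False)
    assigned = np.zeros(n, dtype=bool)
    groups: list[tuple[str, ...]] = []
    perm: list[int] = []
    for i in range(n):
        if assigned[i]:
            continue
        members = np.flatnonzero(linked[i] | (np.arange(n) == i))
        assigned[members] = True
        groups.append(tuple(matrix.labels[j] for j in members))
        perm.extend(int(j) for j in members)
    return ComponentPartition(matrix.labels, tuple(groups), tuple(perm))


def write_labeled_matrix(
    matrix,
    dest: str | Path | IO[str] | None = None,
    labels: Sequence[str] | None = None,
    blocked: bool = False,
    unconnected: str = "zero",
    delimiter: str = ",",
) -> str:
    """Write a square matrix as delimited text with label row and column.

    ``matrix`` may be one of the typed matrices or a plain array with
    ``labels``.  With ``blocked=True`` connected components are first
    collected into diagonal blocks; off-block cells are then rendered
    per ``unconnected``: ``"zero"`` (0), ``"blank"`` (empty cell, the
    published-table presentation) or ``"inf"``.  Returns the text; also
    writes it to ``dest`` when given.
    """
    if labels is None:
        if not hasattr(matrix, "labels"):
            raise ValueError("labels are required for a plain array")
        labels = matrix.labels
    entries = np.asarray(matrix.entries if hasattr(matrix, "entries") else matrix)
    if entries.shape != (len(labels), len(labels)):
        raise ValueError(
            f"matrix shape {entries.shape} does not match {len(labels)} labels"
        )
    labels = tuple(str(x) for x in labels)
    if blocked:
        if not isinstance(matrix, (IndirectConnectionMatrix, DistanceMatrix)):
            raise ValueError("blocked output needs a connection or distance matrix")
        part = _partition_from_matrix(matrix)
        entries, labels = block_sort(matrix, part)
        sizes = [len(g) for g in part.groups]
    else:
        sizes = [len(labels)]

    bounds = np.cumsum([0] + sizes)
    block_of = np.empty(len(labels), dtype=int)
    for b, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        block_of[lo:hi] = b

    def render(i: int, j: int) -> str:
        if block_of[i] != block_of[j] or entries[i, j] == -1:
            if unconnected == "blank":
                return ""
            if unconnected == "inf":
                return "inf"
            return "0"
        return str(int(entries[i, j]))

    buf = _io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow([""] + list(labels))
    for i, lab in enumerate(labels):
        writer.writerow([lab] + [render(i, j) for j in range(len(labels))])
    text = buf.getvalue()
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)
    return text


def read_labeled_matrix(
    source: str | Path | IO[str],
    delimiter: str | None = None,
    unconnected: str = "zero",
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a labeled square matrix written by :func:`write_labeled_matrix`.

    Blank and ``inf`` cells map back to the value implied by
    ``unconnected`` (0 for ``"zero"``/``"blank"``/``"inf"``, or -1 when
    reading a missing-coded matrix with ``unconnected="missing"``).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    if delimiter is None:
        delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    rows = list(csv.reader(_io.StringIO(text), delimiter=delimiter))
    rows = [r for r in rows if r]
    labels = tuple(c.strip() for c in rows[0][1:])
    n = len(labels)
    fill = -1 if unconnected == "missing" else 0
    entries = np.full((n, n), fill, dtype=np.int64)
    if len(rows) != n + 1:
        raise FormatError(f"expected {n} data rows, found {len(rows) - 1}")
    for i, row in enumerate(rows[1:]):
        if row[0].strip() != labels[i]:
            raise FormatError(
                f"row label {row[0]!r} does not match column label {labels[i]!r}"
            )
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell in ("", "inf"):
                continue
            entries[i, j] = int(cell)
    return entries, labels


def write_edge_list(
    network: EvidenceNetwork,
    dest: str | Path | IO[str] | None = None,
    delimiter: str = ",",
) -> str:
    """Write a network's edges as a two-column table (``t_from,t_to``)."""
    buf = _io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(["t_from", "t_to"])
    for a, b in network.edge_pairs():
        writer.writerow([a, b])
    text = buf.getvalue()
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)
    return text
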