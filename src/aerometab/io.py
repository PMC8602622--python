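"""Readers and writers for the pipeline's delimited text formats.

Abundance tables and metadata are CSV or TSV (delimiter auto-detected from the
header line); pathway libraries use the standard GMT layout.  Result writers
emit CSV with a header and stable column order.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AGE_LEVELS,
    CAPACITY_LEVELS,
    AlignmentError,
    FormatError,
    MetaboliteMatrix,
    PathwayLibrary,
    StudyDesign,
)

logger = logging.getLogger("aerometab")


def _sniff_delimiter(header_line: str) -> str:
    """Comma vs. tab, decided from the header line (tab wins when present)."""
    return "\t" if "\t" in header_line else ","


def _read_rectangular(path) -> tuple[list, list]:
    """Read a delimited file into (header, rows), enforcing equal row lengths."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: empty file")
    sep = _sniff_delimiter(lines[0])
    header = lines[0].split(sep)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(sep)
        if len(fields) != len(header):
            raise FormatError(
                f"{path}: ragged row at line {lineno} "
                f"({len(fields)} fields, expected {len(header)})"
            )
        rows.append(fields)
    return header, rows


def read_abundance_table(
    path, tissue: str = "", orientation: str = "samples_in_rows"
) -> MetaboliteMatrix:
    """Read a wide abundance table into samples-in-rows orientation.

    The first column holds row IDs.  With ``orientation='metabolites_in_rows'``
    the table is transposed internally so the result is always samples x
    metabolites.  Non-numeric cells become NaN and their coordinates are
    recorded on the returned matrix.
    """
    if orientation not in ("samples_in_rows", "metabolites_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    header, rows = _read_rectangular(path)
    row_ids = [r[0] for r in rows]
    col_ids = header[1:]
    for ids, what in ((row_ids, "row"), (col_ids, "column")):
        counts = pd.Series(ids).value_counts()
        dups = sorted(counts[counts > 1].index)
        if dups:
            raise FormatError(f"{path}: duplicate {what} IDs: {dups}")
    raw = pd.DataFrame([r[1:] for r in rows], index=row_ids, columns=col_ids)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if orientation == "metabolites_in_rows":
        numeric = numeric.T
    missing = [
        (numeric.index[i], numeric.columns[j])
        for i, j in zip(*np.where(numeric.isna().to_numpy()))
    ]
    if missing:
        logger.warning("%s: %d non-numeric/missing cells", path, len(missing))
    return MetaboliteMatrix(numeric, tissue=tissue, missing_cells=missing)


def write_abundance_table(matrix: MetaboliteMatrix, path) -> None:
    matrix.data.to_csv(path, index_label="sample_id")


def read_design(path) -> StudyDesign:
    """Read sample metadata (sample_id, capacity, age[, speed]).

    Factor levels are validated case-insensitively against HCR/LCR and Y/O
    and normalised to upper case.
    """
    header, rows = _read_rectangular(path)
    cols = [h.strip().lower() for h in header]
    for required in ("sample_id", "capacity", "age"):
        if required not in cols:
            raise FormatError(f"{path}: missing required column '{required}'")
    frame = pd.DataFrame(rows, columns=cols).set_index("sample_id")
    cap = frame["capacity"].str.strip().str.upper()
    age = frame["age"].str.strip().str.upper()
    for sid, level in cap.items():
        if level not in CAPACITY_LEVELS:
            raise FormatError(f"{path}: unknown capacity level {level!r} for sample {sid!r}")
    for sid, level in age.items():
        if level not in AGE_LEVELS:
            raise FormatError(f"{path}: unknown age level {level!r} for sample {sid!r}")
    out = pd.DataFrame({"capacity": cap, "age": age})
    if "speed" in cols:
        out["speed"] = pd.to_numeric(frame["speed"], errors="coerce")
    return StudyDesign(out)


def write_design(design: StudyDesign, path) -> None:
    design.table.to_csv(path, index_label="sample_id")


def read_gmt(path) -> PathwayLibrary:
    """Read a GMT pathway library (name, description, members... per line)."""
    pathways, descriptions = {}, {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.strip() == "":
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}: line {lineno} has {len(fields)} fields; GMT needs "
                "name, description and at least one member"
            )
        name = fields[0]
        if name in pathways:
            raise FormatError(f"{path}: duplicate pathway name {name!r} at line {lineno}")
        pathways[name] = frozenset(m for m in fields[2:] if m != "")
        descriptions[name] = fields[1]
    return PathwayLibrary(pathways, descriptions)


def write_gmt(library: PathwayLibrary, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(library.pathways):
            members = sorted(library.pathways[name])
            desc = library.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + members) + "\n")


def align(matrix: MetaboliteMatrix, design: StudyDesign) -> tuple[MetaboliteMatrix, StudyDesign]:
    """Restrict matrix and design to their common samples, in matrix order.

    Sample IDs are matched case-sensitively.  Dropped samples are logged;
    an empty intersection is an error.
    """
    common = [s for s in matrix.sample_ids if s in set(design.sample_ids)]
    if not common:
        raise AlignmentError("no sample IDs shared between matrix and design")
    dropped = (set(matrix.sample_ids) | set(design.sample_ids)) - set(common)
    if dropped:
        logger.info("align: dropped %d samples not present in both inputs: %s",
                    len(dropped), sorted(dropped))
    return matrix.subset_samples(common), design.subset_samples(common)


def handle_missing(
    matrix: MetaboliteMatrix,
    policy: str = "impute",
    max_missing_frac: float = 0.2,
) -> MetaboliteMatrix:
    """Apply the missing-value policy to an abundance matrix.

    ``impute``: metabolites missing in more than ``max_missing_frac`` of
    samples are dropped with a warning; remaining missing cells are imputed
    as half the metabolite's observed minimum (standard practice for
    below-detection values in targeted panels).  ``error``: any missing cell
    raises.
    """
    if policy not in ("impute", "error"):
        raise ValueError(f"unknown missingness policy {policy!r}")
    data = matrix.data.copy()
    n_missing = data.isna().sum()
    if policy == "error":
        if int(n_missing.sum()) > 0:
            bad = list(n_missing[n_missing > 0].index)
            raise ValueError(f"missing values present (policy=error): {bad}")
        return matrix
    frac = n_missing / len(data)
    drop = list(frac[frac > max_missing_frac].index)
    if drop:
        logger.warning("dropping %d metabolites with >%d%% missing cells: %s",
                       len(drop), int(100 * max_missing_frac), drop)
        data = data.drop(columns=drop)
    for col in data.columns[data.isna().any()]:
        observed_min = data[col].min(skipna=True)
        data[col] = data[col].fillna(observed_min / 2.0)
    return MetaboliteMatrix(data, tissue=matrix.tissue, missing_cells=[])
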