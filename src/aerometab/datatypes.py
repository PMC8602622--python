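"""Shared data model for the two-factor metabolomics pipeline.

The study design is a 2x2 factorial: intrinsic aerobic capacity (HCR = high
capacity runner line vs. LCR = low capacity runner line) crossed with age
(Y = young vs. O = old), with an optional per-sample maximal running speed
(m/min).  Abundance data live in a samples x metabolites matrix per tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CAPACITY_LEVELS = ("HCR", "LCR")
AGE_LEVELS = ("Y", "O")
#: Canonical group order used everywhere (one-hot columns, simulation, reports).
GROUP_ORDER = ("HCR-Y", "LCR-Y", "HCR-O", "LCR-O")

TISSUES = ("serum", "muscle", "wat")


class FormatError(ValueError):
    """A delimited input file violates the expected layout."""


class AlignmentError(ValueError):
    """Sample IDs of a matrix and a design cannot be reconciled."""


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites abundance table with a tissue tag.

    ``data`` holds one row per sample and one column per metabolite, in
    arbitrary abundance units.  ``missing_cells`` records the (sample,
    metabolite) coordinates that were non-numeric or empty on input.
    """

    data: pd.DataFrame
    tissue: str = ""
    missing_cells: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = sorted(set(self.data.index[self.data.index.duplicated()]))
            raise FormatError(f"duplicate sample IDs: {dups}")
        if self.data.columns.duplicated().any():
            dups = sorted(set(self.data.columns[self.data.columns.duplicated()]))
            raise FormatError(f"duplicate metabolite IDs: {dups}")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[1]

    @property
    def all_positive(self) -> bool:
        """True when every cell is present and strictly positive (Box-Cox precondition)."""
        v = self.values
        return bool(np.all(np.isfinite(v)) and np.all(v > 0))

    def subset_samples(self, sample_ids) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            self.data.loc[list(sample_ids)].copy(),
            tissue=self.tissue,
            missing_cells=[c for c in self.missing_cells if c[0] in set(sample_ids)],
        )


@dataclass
class StudyDesign:
    """Per-sample factor levels and (optionally) maximal running speed.

    ``table`` is indexed by sample ID with columns ``capacity`` (HCR/LCR),
    ``age`` (Y/O) and, when available, ``speed`` (m/min, nonnegative).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dups = sorted(set(t.index[t.index.duplicated()]))
            raise FormatError(f"duplicate sample IDs in design: {dups}")
        for col in ("capacity", "age"):
            if col not in t.columns:
                raise FormatError(f"design is missing required column '{col}'")
        bad_cap = ~t["capacity"].isin(CAPACITY_LEVELS)
        if bad_cap.any():
            row = t.index[bad_cap][0]
            raise FormatError(
                f"unknown capacity level {t.loc[row, 'capacity']!r} for sample {row!r}"
            )
        bad_age = ~t["age"].isin(AGE_LEVELS)
        if bad_age.any():
            row = t.index[bad_age][0]
            raise FormatError(f"unknown age level {t.loc[row, 'age']!r} for sample {row!r}")
        if "speed" in t.columns and (t["speed"].dropna() < 0).any():
            raise FormatError("running speed must be nonnegative")

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def capacity(self) -> np.ndarray:
        return self.table["capacity"].to_numpy()

    @property
    def age(self) -> np.ndarray:
        return self.table["age"].to_numpy()

    @property
    def has_speed(self) -> bool:
        return "speed" in self.table.columns and self.table["speed"].notna().all()

    @property
    def speed(self) -> np.ndarray:
        if not self.has_speed:
            raise ValueError("design carries no complete running-speed column")
        return self.table["speed"].to_numpy(dtype=float)

    @property
    def groups(self) -> np.ndarray:
        """Combined capacity-age label per sample, e.g. 'HCR-Y'."""
        return np.array([f"{c}-{a}" for c, a in zip(self.capacity, self.age)])

    def cell_counts(self) -> dict:
        g = self.groups
        return {label: int((g == label).sum()) for label in GROUP_ORDER}

    def require_full_factorial(self) -> None:
        """Raise unless all four capacity x age cells are nonempty."""
        empty = [k for k, v in self.cell_counts().items() if v == 0]
        if empty:
            raise ValueError(f"empty design cells: {empty}; factorial model not identifiable")

    # 0/1 codings used by the simulator and the regression models
    @property
    def capacity_indicator(self) -> np.ndarray:
        """1 for HCR, 0 for LCR (reference)."""
        return (self.capacity == "HCR").astype(float)

    @property
    def age_indicator(self) -> np.ndarray:
        """1 for old, 0 for young (reference)."""
        return (self.age == "O").astype(float)

    def subset_samples(self, sample_ids) -> "StudyDesign":
        return StudyDesign(self.table.loc[list(sample_ids)].copy())


@dataclass
class PathwayLibrary:
    """Mapping from pathway name to a deduplicated set of metabolite IDs."""

    pathways: dict
    descriptions: dict = field(default_factory=dict)
    universe: set | None = None

    def __post_init__(self) -> None:
        clean = {}
        for name, members in self.pathways.items():
            members = frozenset(members)
            if not members:
                raise FormatError(f"pathway {name!r} has no members")
            clean[name] = members
        self.pathways = clean

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.items())
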