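"""Domain types shared across the analysis.

The study design this package models: per donor, five bead-sorted leukocyte
subsets (CD3+ T cells, CD14+ monocytes, CD15+ granulocytes, CD19+ B cells,
CD56+ NK cells) plus an unsorted whole-blood (WB) sample, each profiled on a
miRNA microarray, with donors split into a healthy control group and a lung
cancer group.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_TYPES: tuple[str, ...] = ("WB", "CD3", "CD14", "CD15", "CD19", "CD56")
SUBSETS: tuple[str, ...] = ("CD3", "CD14", "CD15", "CD19", "CD56")
CONDITIONS: tuple[str, ...] = ("control", "cancer")

SCALES = ("linear", "log2")


class LeukomirError(Exception):
    """Base class for validation and integrity errors."""


class IntegrityError(LeukomirError):
    """Input violates a structural invariant (duplicates, misalignment)."""


class ConfigError(LeukomirError):
    """Missing or invalid configuration (columns, enum tokens, parameters)."""


@dataclass
class ExpressionMatrix:
    """miRNA-by-sample expression matrix with an explicit scale tag.

    ``values`` is a DataFrame whose index holds miRNA identifiers and whose
    columns hold sample identifiers.  Linear-scale values are raw (or
    normalized) signal intensities and must be nonnegative; log2-scale values
    are unrestricted.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ConfigError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise IntegrityError(f"duplicate miRNA ids: {dups[:5]}")
        if not self.values.columns.is_unique:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise IntegrityError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise IntegrityError("expression values must be finite")
        if self.scale == "linear" and (arr < 0).any():
            raise IntegrityError("linear-scale expression values must be >= 0")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise IntegrityError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[:, sample_ids].copy(), self.scale)


@dataclass
class DetectionMatrix:
    """Boolean presence/absence calls aligned to an ExpressionMatrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(bool)

    def aligned_with(self, m: ExpressionMatrix) -> bool:
        return list(self.values.index) == m.mirna_ids and list(self.values.columns) == m.sample_ids


@dataclass
class SampleSheet:
    """Per-sample annotation: donor, cell type and condition.

    Every grouping used downstream (condition contrasts, pairwise cell-type
    tests, per-donor mixture fits) is defined by this sheet.
    """

    table: pd.DataFrame  # columns: sample_id, donor_id, cell_type, condition

    REQUIRED = ("sample_id", "donor_id", "cell_type", "condition")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ConfigError(f"sample sheet missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].tolist()
            raise IntegrityError(f"duplicate sample ids: {dups[:5]}")
        bad_ct = sorted(set(self.table["cell_type"]) - set(CELL_TYPES))
        if bad_ct:
            raise ConfigError(f"unknown cell type(s) {bad_ct}; allowed: {list(CELL_TYPES)}")
        bad_cond = sorted(set(self.table["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ConfigError(f"unknown condition(s) {bad_cond}; allowed: {list(CONDITIONS)}")
        pairs = self.table[["donor_id", "cell_type"]]
        if pairs.duplicated().any():
            raise IntegrityError("each (donor, cell_type) may appear at most once")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def donors(self) -> list[str]:
        return sorted(self.table["donor_id"].unique())

    def samples(self, cell_type: str | None = None, condition: str | None = None,
                donor: str | None = None) -> list[str]:
        """Sample ids matching every given criterion (None = no restriction)."""
        t = self.table
        mask = pd.Series(True, index=t.index)
        if cell_type is not None:
            mask &= t["cell_type"] == cell_type
        if condition is not None:
            mask &= t["condition"] == condition
        if donor is not None:
            mask &= t["donor_id"] == donor
        return list(t.loc[mask, "sample_id"])

    def condition_of(self, donor: str) -> str:
        conds = self.table.loc[self.table["donor_id"] == donor, "condition"].unique()
        return conds[0]

    def check_covers(self, m: ExpressionMatrix) -> None:
        missing = set(m.sample_ids) - set(self.sample_ids)
        if missing:
            raise IntegrityError(f"matrix samples missing from sheet: {sorted(missing)[:5]}")


def _default_lineage() -> dict[str, str]:
    return {"CD15": "myeloid", "CD14": "myeloid", "CD3": "lymphoid", "CD19": "lymphoid", "CD56": "lymphoid"}


def _default_defense() -> dict[str, str]:
    return {"CD15": "innate", "CD14": "innate", "CD56": "innate", "CD3": "adaptive", "CD19": "adaptive"}


def _default_function() -> dict[str, str]:
    return {"CD19": "APC", "CD14": "APC", "CD3": "cytotoxic", "CD56": "cytotoxic"}


@dataclass
class CellTypeOntology:
    """Three biological groupings of the five sorted subsets.

    lineage: myeloid (CD15, CD14) vs lymphoid (CD3, CD19, CD56) progenitor;
    defense: innate (CD15, CD14, CD56) vs adaptive (CD3, CD19) immunity;
    function: antigen-presenting (CD19, CD14) vs cytotoxic (CD3, CD56) cells.
    Whole blood belongs to none of the maps.
    """

    lineage: dict[str, str] = field(default_factory=_default_lineage)
    defense: dict[str, str] = field(default_factory=_default_defense)
    function: dict[str, str] = field(default_factory=_default_function)

    AXES = ("lineage", "defense", "function")
    # canonical (side_a, side_b) label order per axis
    SIDE_LABELS = {
        "lineage": ("myeloid", "lymphoid"),
        "defense": ("innate", "adaptive"),
        "function": ("APC", "cytotoxic"),
    }

    def __post_init__(self) -> None:
        for axis in self.AXES:
            mapping = getattr(self, axis)
            if "WB" in mapping:
                raise ConfigError("WB must not appear in ontology maps")
            covered = set(mapping)
            if not covered.issubset(set(SUBSETS)):
                raise ConfigError(f"{axis} map contains unknown cell types: {covered - set(SUBSETS)}")

    def sides(self, axis: str) -> tuple[list[str], list[str]]:
        """Cell types on each side of an axis, in canonical label order."""
        if axis not in self.AXES:
            raise ConfigError(f"unknown axis {axis!r}; allowed: {list(self.AXES)}")
        mapping = getattr(self, axis)
        la, lb = self.SIDE_LABELS[axis]
        side_a = sorted(c for c, g in mapping.items() if g == la)
        side_b = sorted(c for c, g in mapping.items() if g == lb)
        return side_a, side_b


@dataclass
class ProbeTable:
    """Long-format probe-level signals, 40 replicate probes per miRNA on the
    array design this emulates."""

    records: pd.DataFrame  # columns: probe_id, mirna_id, sample_id, signal[, detected]

    REQUIRED = ("probe_id", "mirna_id", "sample_id", "signal")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ConfigError(f"probe table missing columns: {missing}")
        if self.records[["probe_id", "sample_id"]].duplicated().any():
            dup = self.records[self.records[["probe_id", "sample_id"]].duplicated()]
            raise IntegrityError(
                f"duplicate (probe_id, sample_id) pairs, e.g. {dup.iloc[0]['probe_id']}/{dup.iloc[0]['sample_id']}")
        sig = self.records["signal"].to_numpy(dtype=float)
        if not np.isfinite(sig).all() or (sig < 0).any():
            raise IntegrityError("probe signals must be finite and >= 0")

    @property
    def has_detection_flag(self) -> bool:
        return "detected" in self.records.columns

    def __len__(self) -> int:
        return len(self.records)
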