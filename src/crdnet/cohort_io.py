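"""Reading, writing and preprocessing of component-resolved diagnostics (CRD) data.

A CRD matrix holds multiplexed serum specific-IgE measurements: rows are
participants, columns are allergen components (e.g. ``Der p 1``), entries are
non-negative continuous values in ISAC Standardised Units (ISU).  This module
provides the containers and the standard preprocessing chain:

1. dichotomisation at the manufacturer positivity cut-off (> 0.30 ISU),
2. activity filtering (keep components positive in >= 5% of participants and
   participants positive to at least one retained component),
3. the ``log(x + 1)`` transform used by all continuous downstream analyses.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ISAC positivity cut-off in ISU; a response is positive when strictly above it.
POSITIVITY_THRESHOLD = 0.30

#: Minimum fraction of participants that must be positive for a component to
#: count as "active".
MIN_PREVALENCE = 0.05


class CohortError(ValueError):
    """Raised for malformed or contract-violating cohort data."""


def _check_unique(ids: Sequence, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise CohortError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class CRDMatrix:
    """Participants x components matrix of continuous ISU values.

    ``data`` is a float DataFrame indexed by participant id with component
    names as columns.  Entries must be finite and non-negative; missing values
    are rejected unless they were explicitly imputed to zero at read time.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0:
            raise CohortError("no participants")
        if self.data.shape[1] == 0:
            raise CohortError("no components")
        _check_unique(self.data.index, "participant ids")
        _check_unique(self.data.columns, "component ids")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise CohortError(
                "missing or non-finite ISU value at participant "
                f"{self.data.index[bad[0]]!r}, component {self.data.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise CohortError(
                "negative ISU value at participant "
                f"{self.data.index[bad[0]]!r}, component {self.data.columns[bad[1]]!r}"
            )

    @property
    def participant_ids(self) -> list:
        return list(self.data.index)

    @property
    def component_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class BinaryProfile:
    """Dichotomised sensitisation matrix; entries in {0, 1}."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise CohortError("binary profile entries must be 0 or 1")
        self.data = self.data.astype(np.int8)

    @property
    def participant_ids(self) -> list:
        return list(self.data.index)

    @property
    def component_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.int8)


@dataclass
class OutcomeTable:
    """Per-participant clinical outcomes.

    ``binary`` holds 0/1 flags (asthma is mandatory; wheeze, rhinitis, AD are
    optional); ``continuous`` holds optional lung-function columns.
    """

    binary: pd.DataFrame
    continuous: pd.DataFrame = field(default_factory=pd.DataFrame)

    BINARY_OUTCOMES = ("asthma", "wheeze", "rhinitis", "ad")

    def __post_init__(self) -> None:
        if "asthma" not in self.binary.columns:
            raise CohortError("outcome table must contain an 'asthma' column")
        _check_unique(self.binary.index, "participant ids")
        for col in self.binary.columns:
            vals = self.binary[col].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise CohortError(f"binary outcome {col!r} has values outside {{0,1}}")
        self.binary = self.binary.astype(np.int8)
        if len(self.continuous) and not self.continuous.index.equals(self.binary.index):
            raise CohortError("continuous outcomes must share the binary index")

    @property
    def participant_ids(self) -> list:
        return list(self.binary.index)

    def aligned_to(self, ids: Sequence) -> "OutcomeTable":
        """Subset and reorder to ``ids``; every id must be present."""
        missing = [i for i in ids if i not in self.binary.index]
        if missing:
            raise CohortError(f"outcomes missing for participants {missing[:5]}")
        cont = self.continuous.loc[ids] if len(self.continuous) else self.continuous
        return OutcomeTable(self.binary.loc[ids], cont)


@dataclass
class FilterReport:
    """Bookkeeping for the activity-filtering step."""

    n_before: int
    n_after: int
    p_before: int
    p_after: int
    dropped_components: list

    def to_dict(self) -> dict:
        return {
            "n_before": self.n_before,
            "n_after": self.n_after,
            "p_before": self.p_before,
            "p_after": self.p_after,
            "dropped_components": list(self.dropped_components),
        }


def _sniff_sep(path: Path) -> str:
    header = path.open("r").readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_crd(path, sep: str | None = None, missing_to_zero: bool = False) -> CRDMatrix:
    """Read a delimited CRD file (participant ids in the first column).

    The delimiter is sniffed from the header (comma or tab) unless given.
    Missing cells raise by default; ``missing_to_zero=True`` maps them to 0
    (ISAC reports below-detection responses as 0) and logs how many were set.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"input file not found: {path}")
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.shape[0] == 0:
        raise CohortError(f"no participants in {path}")
    if missing_to_zero:
        n_missing = int(df.isna().sum().sum())
        if n_missing:
            logger.warning("imputing %d missing ISU cells to 0 in %s", n_missing, path)
            df = df.fillna(0.0)
    non_numeric = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        row = df[pd.to_numeric(df[col], errors="coerce").isna()].index
        raise CohortError(
            f"non-numeric value in column {col!r}"
            + (f", row {row[0]!r}" if len(row) else "")
        )
    m = CRDMatrix(df.astype(float))
    logger.info("read CRD matrix: n=%d participants, p=%d components", *m.shape)
    return m


def write_crd(m: CRDMatrix | BinaryProfile, path, sep: str = ",") -> None:
    """Write a matrix in the same dialect :func:`read_crd` accepts."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    m.data.to_csv(path, sep=sep, index_label="participant_id")


def read_outcomes(path, sep: str | None = None) -> OutcomeTable:
    """Read an outcomes table; binary flag columns plus optional continuous ones."""
    path = Path(path)
    if not path.exists():
        raise CohortError(f"input file not found: {path}")
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    binary_cols = [c for c in df.columns if c.lower() in OutcomeTable.BINARY_OUTCOMES]
    cont_cols = [c for c in df.columns if c not in binary_cols]
    binary = df[binary_cols].rename(columns=str.lower)
    continuous = df[cont_cols].astype(float) if cont_cols else pd.DataFrame()
    return OutcomeTable(binary, continuous)


def write_outcomes(t: OutcomeTable, path, sep: str = ",") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.concat([t.binary, t.continuous], axis=1) if len(t.continuous) else t.binary
    df.to_csv(path, sep=sep, index_label="participant_id")


def dichotomise(m: CRDMatrix, threshold: float = POSITIVITY_THRESHOLD) -> BinaryProfile:
    """Binarise ISU values: positive iff strictly greater than ``threshold``.

    Ties at exactly the threshold are negative, matching the "> 0.30 ISU"
    positivity convention of the ISAC assay.
    """
    if threshold <= 0:
        raise CohortError("positivity threshold must be > 0")
    return BinaryProfile((m.data > threshold).astype(np.int8))


def filter_active(
    b: BinaryProfile,
    m: CRDMatrix | None = None,
    min_prevalence: float = MIN_PREVALENCE,
) -> tuple[BinaryProfile, CRDMatrix | None, FilterReport]:
    """Keep active components and sensitised participants.

    A component is *active* when its positivity fraction over the *pre-filter*
    participant count is ``>= min_prevalence`` (inclusive).  A participant is
    retained when positive to at least one active component.  When the paired
    continuous matrix ``m`` is supplied it is subset identically.
    """
    n_before, p_before = b.shape
    if m is not None and (m.participant_ids != b.participant_ids or m.component_ids != b.component_ids):
        raise CohortError("binary profile and CRD matrix axes do not match")
    prevalence = b.data.mean(axis=0)
    active = prevalence[prevalence >= min_prevalence].index
    if len(active) == 0:
        raise CohortError("no active components after prevalence filtering")
    sub = b.data[active]
    keep = sub.sum(axis=1) > 0
    if not keep.any():
        raise CohortError("no participants positive to any active component")
    dropped = [c for c in b.component_ids if c not in set(active)]
    filtered_b = BinaryProfile(sub.loc[keep])
    filtered_m = CRDMatrix(m.data.loc[keep, active]) if m is not None else None
    report = FilterReport(
        n_before=n_before,
        n_after=int(keep.sum()),
        p_before=p_before,
        p_after=len(active),
        dropped_components=dropped,
    )
    logger.info(
        "activity filter: %d/%d components active, %d/%d participants retained",
        report.p_after, p_before, report.n_after, n_before,
    )
    return filtered_b, filtered_m, report


def log1_transform(m: CRDMatrix) -> CRDMatrix:
    """Entrywise ``log(x + 1)``; the transform used before all density work."""
    return CRDMatrix(np.log1p(m.data))


def inverse_log1_transform(m: CRDMatrix) -> CRDMatrix:
    return CRDMatrix(np.expm1(m.data))
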