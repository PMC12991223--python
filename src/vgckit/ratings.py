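"""Data model, validation and CSV I/O for multi-reader multi-case rating panels.

A visual grading study collects one ordinal image-quality rating per
(observer, case, protocol, criterion) cell.  The panel is *complete* by
design: every observer rates every case under every protocol for every
criterion.  This module holds the validated in-memory container
(:class:`RatingPanel`) and the long-format CSV reader/writer used to exchange
panels with observer-study logging software.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "RatingRecord",
    "RatingPanel",
    "PanelValidationError",
    "CompletenessError",
    "DuplicateKeyError",
    "RatingRangeError",
    "read_ratings",
    "write_ratings",
    "read_class_map",
    "default_class_map",
]

#: Canonical column order of the long ("tidy") ratings CSV.
RATING_COLUMNS = ("observer", "case", "protocol", "criterion", "rating")


class PanelValidationError(ValueError):
    """A rating panel violated one of its structural invariants."""


class CompletenessError(PanelValidationError):
    """A (observer, case, protocol, criterion) cell is missing.

    ``key`` names the first missing cell in lexicographic order.
    """

    def __init__(self, key: tuple[str, str, str, str]):
        self.key = key
        super().__init__(
            "panel is incomplete: missing rating for "
            f"(observer={key[0]!r}, case={key[1]!r}, "
            f"protocol={key[2]!r}, criterion={key[3]!r})"
        )


class DuplicateKeyError(PanelValidationError):
    """More than one rating shares the same design cell."""

    def __init__(self, key: tuple[str, str, str, str]):
        self.key = key
        super().__init__(
            "duplicate rating for "
            f"(observer={key[0]!r}, case={key[1]!r}, "
            f"protocol={key[2]!r}, criterion={key[3]!r})"
        )


class RatingRangeError(PanelValidationError):
    """A rating falls outside the declared ordinal scale [1, K]."""

    def __init__(self, rating, n_categories: int):
        self.rating = rating
        self.n_categories = n_categories
        super().__init__(
            f"rating {rating!r} outside the declared scale [1, {n_categories}]"
        )


@dataclass(frozen=True)
class RatingRecord:
    """One ordinal rating of one image series by one observer."""

    observer_id: str
    case_id: str
    protocol_id: str
    criterion_id: str
    rating: int

    def __post_init__(self):
        for name in ("observer_id", "case_id", "protocol_id", "criterion_id"):
            if not str(getattr(self, name)):
                raise PanelValidationError(f"{name} must be non-empty")


@dataclass(frozen=True)
class RatingPanel:
    """A complete multi-reader multi-case ordinal rating panel.

    Parameters
    ----------
    data
        Long-format frame with columns ``observer, case, protocol,
        criterion, rating``; id columns are strings, ratings integers.
    n_categories
        Declared number of ordinal categories K.  Declared rather than
        inferred so that a panel in which an extreme category is never used
        is still valid; the VGC operating points depend on K.
    """

    data: pd.DataFrame
    n_categories: int = 5

    def __post_init__(self):
        df = self.data
        if self.n_categories < 2:
            raise PanelValidationError("n_categories must be at least 2")
        missing_cols = [c for c in RATING_COLUMNS if c not in df.columns]
        if missing_cols:
            raise PanelValidationError(f"missing columns: {missing_cols}")
        if len(df) == 0:
            raise PanelValidationError("panel must contain at least one record")

        df = df.loc[:, list(RATING_COLUMNS)].copy()
        for c in RATING_COLUMNS[:-1]:
            df[c] = df[c].astype(str)
            if (df[c] == "").any():
                raise PanelValidationError(f"empty label in column {c!r}")
        ratings = pd.to_numeric(df["rating"], errors="raise")
        if not (ratings == ratings.round()).all():
            raise RatingRangeError(
                df["rating"][ratings != ratings.round()].iloc[0], self.n_categories
            )
        df["rating"] = ratings.astype(int)
        bad = (df["rating"] < 1) | (df["rating"] > self.n_categories)
        if bad.any():
            raise RatingRangeError(int(df["rating"][bad].iloc[0]), self.n_categories)

        key_cols = list(RATING_COLUMNS[:-1])
        dup = df.duplicated(subset=key_cols, keep="first")
        if dup.any():
            raise DuplicateKeyError(tuple(df.loc[dup.idxmax(), key_cols]))

        full = (
            len(self.observers_of(df))
            * len(self.cases_of(df))
            * len(self.protocols_of(df))
            * len(self.criteria_of(df))
        )
        if len(df) != full:
            have = set(map(tuple, df[key_cols].itertuples(index=False)))
            for key in itertools.product(
                self.observers_of(df),
                self.cases_of(df),
                self.protocols_of(df),
                self.criteria_of(df),
            ):
                if key not in have:
                    raise CompletenessError(key)

        df = df.sort_values(key_cols, kind="stable").reset_index(drop=True)
        object.__setattr__(self, "data", df)

    @staticmethod
    def observers_of(df: pd.DataFrame) -> list[str]:
        return sorted(df["observer"].unique())

    @staticmethod
    def cases_of(df: pd.DataFrame) -> list[str]:
        return sorted(df["case"].unique())

    @staticmethod
    def protocols_of(df: pd.DataFrame) -> list[str]:
        return sorted(df["protocol"].unique())

    @staticmethod
    def criteria_of(df: pd.DataFrame) -> list[str]:
        return sorted(df["criterion"].unique())

    @property
    def observers(self) -> list[str]:
        return self.observers_of(self.data)

    @property
    def cases(self) -> list[str]:
        return self.cases_of(self.data)

    @property
    def protocols(self) -> list[str]:
        return self.protocols_of(self.data)

    @property
    def criteria(self) -> list[str]:
        return self.criteria_of(self.data)

    @property
    def records(self) -> list[RatingRecord]:
        return [
            RatingRecord(r.observer, r.case, r.protocol, r.criterion, int(r.rating))
            for r in self.data.itertuples(index=False)
        ]

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RatingPanel):
            return NotImplemented
        return self.n_categories == other.n_categories and self.data.equals(other.data)

    def ratings(
        self,
        observer: str | None = None,
        protocol: str | None = None,
        criteria=None,
    ) -> pd.Series:
        """Ratings filtered by observer, protocol and/or a criterion subset."""
        df = self.data
        mask = pd.Series(True, index=df.index)
        if observer is not None:
            mask &= df["observer"] == observer
        if protocol is not None:
            mask &= df["protocol"] == protocol
        if criteria is not None:
            mask &= df["criterion"].isin(list(criteria))
        return df.loc[mask, "rating"]


def read_ratings(path: str | Path, n_categories: int = 5) -> RatingPanel:
    """Read a long-format ratings CSV and return a validated panel.

    The file must carry the header ``observer,case,protocol,criterion,rating``.
    Completeness, duplicate-key and rating-range checks are applied; the
    first violation raises the corresponding :class:`PanelValidationError`
    subclass naming the offending cell.
    """
    df = pd.read_csv(path, dtype={c: str for c in RATING_COLUMNS[:-1]})
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"{path}: missing columns {missing}")
    return RatingPanel(df, n_categories=n_categories)


def write_ratings(panel: RatingPanel, path: str | Path) -> None:
    """Write a panel to long-format CSV (deterministic row order, UTF-8).

    Round-trip identity: ``read_ratings(write_ratings(p))`` reproduces ``p``
    record for record.
    """
    if len(panel) == 0:  # unreachable through the validated constructor
        raise PanelValidationError("refusing to write an empty panel")
    panel.data.to_csv(path, index=False, lineterminator="\n")


def read_class_map(path: str | Path) -> dict[str, str]:
    """Read a ``criterion,class`` CSV into an ordered criterion→class map."""
    df = pd.read_csv(path, dtype=str)
    for col in ("criterion", "class"):
        if col not in df.columns:
            raise PanelValidationError(f"{path}: class map must have column {col!r}")
    dup = df["criterion"].duplicated()
    if dup.any():
        raise PanelValidationError(
            f"{path}: duplicate criterion {df['criterion'][dup].iloc[0]!r}"
        )
    return dict(zip(df["criterion"], df["class"]))


def default_class_map() -> dict[str, str]:
    """The study's grouping of the 14 quality criteria into 4 classes.

    Q1–Q5 vessel demarcation, Q6–Q10 vessel disturbance, Q11–Q12 bone
    structure, Q13–Q14 tumor homogeneity.
    """
    with resources.files("vgckit.data").joinpath("criterion_classes.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    return dict(zip(df["criterion"], df["class"]))
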