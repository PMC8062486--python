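"""Observation records (one dead rabbit each) and their CSV representation.

A record carries the subspecies label, the age in days, the lens dry weight
in mg, an optional body weight in g, and a provenance flag distinguishing
exactly-known ages (animals born in monitored cages) from ages estimated
from juvenile body weight (animals first trapped in enclosures).

CSV dialect: comma-separated, header row, UTF-8, '.' decimal, columns
``id, group, age_days, ldw_mg, body_weight_g, age_known``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ObservationRecord",
    "ObservationSet",
    "read_observations",
    "write_observations",
]

REQUIRED_COLUMNS = ("id", "group", "age_days", "ldw_mg")
OPTIONAL_COLUMNS = ("body_weight_g", "age_known")


@dataclass(frozen=True)
class ObservationRecord:
    """One rabbit: group label, age (days), lens dry weight (mg)."""

    id: str
    group: str
    age_days: float
    ldw_mg: float
    body_weight_g: float | None = None
    age_known: bool = True

    def __post_init__(self) -> None:
        if not self.age_days > 0:
            raise ValueError(f"record {self.id!r}: age_days={self.age_days} must be > 0")
        if not self.ldw_mg > 0:
            raise ValueError(f"record {self.id!r}: ldw_mg={self.ldw_mg} must be > 0")
        if self.body_weight_g is not None and not self.body_weight_g > 0:
            raise ValueError(
                f"record {self.id!r}: body_weight_g={self.body_weight_g} must be > 0"
            )


@dataclass(frozen=True)
class ObservationSet:
    """A validated, ordered collection of observation records.

    ``groups`` declares the admissible group labels; every record must use
    one of them.  Arrays for fitting are exposed via :meth:`ages`,
    :meth:`ldw` and :meth:`group_labels`.
    """

    records: tuple[ObservationRecord, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValueError("ObservationSet must contain at least one record")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError(f"duplicate group labels in {self.groups}")
        declared = set(self.groups)
        undeclared = sorted({r.group for r in self.records} - declared)
        if undeclared:
            raise ValueError(
                f"records use undeclared group labels {undeclared}; declared: "
                f"{list(self.groups)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def ages(self) -> np.ndarray:
        return np.array([r.age_days for r in self.records], dtype=float)

    def ldw(self) -> np.ndarray:
        return np.array([r.ldw_mg for r in self.records], dtype=float)

    def group_labels(self) -> np.ndarray:
        return np.array([r.group for r in self.records], dtype=object)

    def group_counts(self) -> dict[str, int]:
        labels = [r.group for r in self.records]
        return {g: labels.count(g) for g in self.groups}

    def subset(self, indices) -> "ObservationSet":
        """New set with the records at ``indices`` (groups unchanged)."""
        recs = tuple(self.records[int(i)] for i in np.atleast_1d(indices))
        return ObservationSet(records=recs, groups=self.groups)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "group": [r.group for r in self.records],
                "age_days": [r.age_days for r in self.records],
                "ldw_mg": [r.ldw_mg for r in self.records],
                "body_weight_g": [r.body_weight_g for r in self.records],
                "age_known": [r.age_known for r in self.records],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, groups=None) -> "ObservationSet":
        """Build a validated set from a DataFrame with the CSV schema.

        Raises ValueError listing every offending row and field.  Extra
        columns are ignored with a warning.  ``groups`` defaults to the
        labels present, in order of first appearance.
        """
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        extra = [c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
        if extra:
            warnings.warn(f"ignoring unrecognized columns: {extra}", stacklevel=2)

        problems: list[str] = []
        records: list[ObservationRecord] = []
        for row_no, row in enumerate(df.itertuples(index=False), start=1):
            d = row._asdict()
            bw = d.get("body_weight_g")
            if bw is not None and (pd.isna(bw)):
                bw = None
            ak = d.get("age_known", True)
            if pd.isna(ak):
                ak = True
            try:
                records.append(
                    ObservationRecord(
                        id=str(d["id"]),
                        group=str(d["group"]),
                        age_days=float(d["age_days"]),
                        ldw_mg=float(d["ldw_mg"]),
                        body_weight_g=None if bw is None else float(bw),
                        age_known=bool(ak),
                    )
                )
            except (ValueError, TypeError) as exc:
                problems.append(f"row {row_no}: {exc}")
        if problems:
            raise ValueError("invalid observation rows:\n" + "\n".join(problems))

        if groups is None:
            seen: list[str] = []
            for r in records:
                if r.group not in seen:
                    seen.append(r.group)
            groups = tuple(seen)
        return cls(records=tuple(records), groups=tuple(groups))


def read_observations(path, groups=None) -> ObservationSet:
    """Read and validate an observation CSV (see module docstring for schema)."""
    df = pd.read_csv(path)
    return ObservationSet.from_dataframe(df, groups=groups)


def write_observations(obs: ObservationSet, path) -> None:
    """Write the observation CSV; deterministic byte-for-byte for equal data."""
    df = obs.to_dataframe()
    # repr-style float formatting keeps round trips lossless and output stable
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
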