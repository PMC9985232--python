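"""Twin cohort container: per-individual phenotype rows linked into MZ pairs.

The cohort table has one row per individual, indexed by ``individual_id``,
with columns::

    pair_id     str     each pair_id appears exactly twice
    twin_index  int     1 or 2 within the pair
    sex         str     'F' or 'M' (shared within an MZ pair)
    age_years   float   shared within a pair
    sbp1..sbp3  float   three repeated systolic readings (mmHg)
    dbp1..dbp3  float   three repeated diastolic readings (mmHg)
    bmi, tg, fbg        optional metabolic covariates
    case_status bool    optional hypertension case indicator

Phenotype derivation (averaging the repeated readings, outlier removal,
discordant-pair selection) lives in :mod:`twinewas.preprocess`.
"""
from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "pair_id",
    "twin_index",
    "sex",
    "age_years",
    "sbp1",
    "sbp2",
    "sbp3",
    "dbp1",
    "dbp2",
    "dbp3",
)

TRAITS = ("SBP", "DBP")


def reading_columns(trait: str) -> list[str]:
    trait = trait.upper()
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    return [f"{trait.lower()}{i}" for i in (1, 2, 3)]


def derived_column(trait: str) -> str:
    trait = trait.upper()
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    return trait.lower()


class TwinCohort:
    """Validated per-individual phenotype table for MZ twin pairs."""

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "individual_id" in table.columns:
            table = table.set_index("individual_id")
        table.index = table.index.astype(str)
        table.index.name = "individual_id"
        missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        table["pair_id"] = table["pair_id"].astype(str)
        table["twin_index"] = table["twin_index"].astype(int)
        self._validate_pairs(table)
        # canonical ordering: pair blocks, twin 1 before twin 2
        table = table.sort_values(["pair_id", "twin_index"], kind="stable")
        self.table = table

    @staticmethod
    def _validate_pairs(table: pd.DataFrame) -> None:
        counts = table.groupby("pair_id")["twin_index"].agg(["count", "min", "max"])
        bad = counts[(counts["count"] != 2) | (counts["min"] != 1) | (counts["max"] != 2)]
        if len(bad):
            raise ValueError(
                "each pair_id must appear exactly twice with twin_index {1,2}; "
                f"offending pairs: {list(bad.index[:5])}"
            )
        ages = table.groupby("pair_id")["age_years"].nunique()
        unequal = ages[ages > 1]
        if len(unequal):
            raise ValueError(
                f"co-twins must share age; offending pairs: {list(unequal.index[:5])}"
            )

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def individual_ids(self) -> pd.Index:
        return self.table.index

    @property
    def pair_ids(self) -> np.ndarray:
        return self.table["pair_id"].unique()

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def pair_rows(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (twin-1 rows, twin-2 rows) aligned by pair_id."""
        t1 = self.table[self.table["twin_index"] == 1].set_index("pair_id")
        t2 = self.table[self.table["twin_index"] == 2].set_index("pair_id")
        t2 = t2.loc[t1.index]
        return t1, t2

    def subset_pairs(self, pair_ids: Iterable[str]) -> "TwinCohort":
        keep = self.table["pair_id"].isin(set(pair_ids))
        return TwinCohort(self.table[keep].reset_index())

    def with_columns(self, **cols) -> "TwinCohort":
        table = self.table.copy()
        for name, values in cols.items():
            table[name] = values
        return TwinCohort(table.reset_index())

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "TwinCohort":
        return cls(pd.read_csv(path, dtype={"pair_id": str, "individual_id": str}))

    def to_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TwinCohort({self.n_pairs} pairs, {len(self)} individuals)"
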