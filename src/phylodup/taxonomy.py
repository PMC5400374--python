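"""Species-to-rank membership table driving the monophyly screens.

Each species is assigned to genus, tribe, subfamily, family and order.
Higher ranks may be empty for sparsely annotated outgroups, but the
nesting must be consistent: two species that share a genus must share
every higher rank that is defined for both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

RANKS = ("genus", "tribe", "subfamily", "family", "order")


@dataclass
class TaxonomyTable:
    """Maps ``species_id`` to its membership at each taxonomic rank."""

    rows: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in ("species_id",) + RANKS if c not in df.columns]
        if missing:
            raise ValueError(f"taxonomy table missing columns: {missing}")
        if df["species_id"].duplicated().any():
            dupes = sorted(df.loc[df["species_id"].duplicated(), "species_id"])
            raise ValueError(f"duplicate species_id entries: {dupes}")
        self.rows = df.fillna("").astype(str).reset_index(drop=True)
        self._check_nesting()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, str]]) -> "TaxonomyTable":
        return cls(pd.DataFrame.from_records(list(records)))

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def _check_nesting(self) -> None:
        # walking up RANKS, species agreeing at a lower rank must agree at
        # every higher rank where both are annotated
        for lo_i, lo in enumerate(RANKS[:-1]):
            for hi in RANKS[lo_i + 1 :]:
                sub = self.rows[(self.rows[lo] != "") & (self.rows[hi] != "")]
                n_hi = sub.groupby(lo)[hi].nunique()
                bad = n_hi[n_hi > 1]
                if not bad.empty:
                    raise ValueError(
                        f"rank nesting violated: {lo} group(s) {list(bad.index)} "
                        f"span multiple {hi} values"
                    )

    # -- queries --------------------------------------------------------------

    @property
    def species(self) -> set[str]:
        return set(self.rows["species_id"])

    def rank_of(self, species_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        hit = self.rows.loc[self.rows["species_id"] == species_id, rank]
        if hit.empty:
            raise KeyError(f"unknown species {species_id!r}")
        return hit.iloc[0]

    def groups(self, rank: str) -> dict[str, set[str]]:
        """Group label -> species set at ``rank`` (empty labels skipped)."""
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        out: dict[str, set[str]] = {}
        for label, sub in self.rows.groupby(rank):
            if label:
                out[label] = set(sub["species_id"])
        return out

    def species_of_groups(self, labels: Iterable[str]) -> set[str]:
        """Union of species in any of the named groups, at any rank."""
        wanted = set(labels)
        out: set[str] = set()
        for rank in RANKS:
            grp = self.groups(rank)
            for label in wanted & set(grp):
                out |= grp[label]
        # a bare species_id can also name itself as a group
        out |= wanted & self.species
        return out
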