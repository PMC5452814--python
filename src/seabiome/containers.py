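"""In-memory containers for OTU tables, sample metadata and reaction records.

The count table is a thin wrapper over a taxa-by-samples integer matrix with
aligned label lists; distance matrices use :class:`skbio.DistanceMatrix` and
phylogenies use :class:`skbio.TreeNode` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DomainError

COMMUNITY_TYPES = ("leaf", "root", "water", "sediment")


@dataclass
class OtuTable:
    """Nonnegative integer count matrix, rows = taxa, columns = samples."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DomainError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise DomainError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise DomainError("counts must be nonnegative")
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        nt, ns = self.counts.shape
        if len(self.taxon_ids) != nt:
            raise DomainError(
                f"{len(self.taxon_ids)} taxon ids for {nt} matrix rows"
            )
        if len(self.sample_ids) != ns:
            raise DomainError(
                f"{len(self.sample_ids)} sample ids for {ns} matrix columns"
            )
        if len(set(self.taxon_ids)) != nt:
            raise DomainError("duplicate taxon ids")
        if len(set(self.sample_ids)) != ns:
            raise DomainError("duplicate sample ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.taxon_ids, columns=self.sample_ids
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])

    def select_taxa(self, taxon_ids: list[str]) -> "OtuTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return OtuTable(list(taxon_ids), list(self.sample_ids), self.counts[idx, :])

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def taxon_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class SampleRecord:
    """One sample's grouping factors: compartment, bed nested within site."""

    sample_id: str
    community_type: str
    bed_id: str
    site_id: str

    def __post_init__(self) -> None:
        if self.community_type not in COMMUNITY_TYPES:
            raise DomainError(
                f"community_type {self.community_type!r} not one of "
                f"{COMMUNITY_TYPES}"
            )


class SampleMetadata:
    """Mapping sample_id -> SampleRecord with bed-within-site nesting."""

    def __init__(self, records: list[SampleRecord]):
        self._records: dict[str, SampleRecord] = {}
        bed_site: dict[str, str] = {}
        for r in records:
            if r.sample_id in self._records:
                raise DomainError(f"duplicate metadata for sample {r.sample_id!r}")
            if r.bed_id in bed_site and bed_site[r.bed_id] != r.site_id:
                raise DomainError(
                    f"bed {r.bed_id!r} appears in sites "
                    f"{bed_site[r.bed_id]!r} and {r.site_id!r}"
                )
            bed_site[r.bed_id] = r.site_id
            self._records[r.sample_id] = r

    def __getitem__(self, sample_id: str) -> SampleRecord:
        return self._records[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def sample_ids(self) -> list[str]:
        return list(self._records)

    def community_types(self, sample_ids: list[str]) -> list[str]:
        return [self._records[s].community_type for s in sample_ids]

    def bed_ids(self, sample_ids: list[str]) -> list[str]:
        return [self._records[s].bed_id for s in sample_ids]

    def site_ids(self, sample_ids: list[str]) -> list[str]:
        return [self._records[s].site_id for s in sample_ids]

    def samples_of_type(self, community_type: str) -> list[str]:
        return [
            s for s, r in self._records.items()
            if r.community_type == community_type
        ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "community_type": r.community_type,
                    "bed_id": r.bed_id,
                    "site_id": r.site_id,
                }
                for r in self._records.values()
            ]
        ).set_index("sample_id")


@dataclass(frozen=True)
class ReactionRecord:
    """One metabolic reaction: substrate compounds -> product compounds."""

    reaction_id: str
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.substrates:
            raise DomainError(f"reaction {self.reaction_id!r}: empty substrates")
        if not self.products:
            raise DomainError(f"reaction {self.reaction_id!r}: empty products")
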