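"""Core containers: protein sequence records and labelled pair datasets.

A :class:`ProteinRecord` is an identifier plus an amino-acid string over the
20-letter alphabet (non-standard letters such as B/J/O/U/X/Z are permitted on
input; the encoders decide how to treat them).  A :class:`PairDataset` is a
list of unordered protein-identifier pairs with a 0/1 interaction label — the
supervised unit of a PPI prediction task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

LOCALIZATIONS = (
    "cytoplasm",
    "nucleus",
    "mitochondrion",
    "endoplasmic reticulum",
    "Golgi apparatus",
    "peroxisome",
    "vacuole",
    "other",
)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an optional subcellular localization label."""

    id: str
    seq: str
    localization: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.seq:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


class ProteinCollection:
    """An ordered, id-unique collection of :class:`ProteinRecord`."""

    def __init__(self, records: Iterable[ProteinRecord] = ()) -> None:
        self._by_id: dict[str, ProteinRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: ProteinRecord) -> None:
        if rec.id in self._by_id:
            raise ValueError(f"duplicate protein id {rec.id!r}")
        self._by_id[rec.id] = rec

    def __getitem__(self, pid: str) -> ProteinRecord:
        return self._by_id[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self._by_id

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def ids(self) -> list[str]:
        return list(self._by_id)

    def with_localizations(self, table: dict[str, str]) -> "ProteinCollection":
        """Return a copy where each record carries its localization label."""
        out = ProteinCollection()
        for rec in self:
            out.add(
                ProteinRecord(rec.id, rec.seq, table.get(rec.id, rec.localization))
            )
        return out


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered-pair convention: lexicographically smaller id first."""
    return (a, b) if a <= b else (b, a)


@dataclass
class PairDataset:
    """Labelled protein pairs; (A, B) and (B, A) are the same pair."""

    pairs: list[tuple[str, str, int]] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], int] = {}
        canon: list[tuple[str, str, int]] = []
        for a, b, y in self.pairs:
            if y not in (0, 1):
                raise ValueError(f"label must be 0 or 1, got {y!r}")
            key = canonical_pair(a, b)
            if key in seen:
                if seen[key] != y:
                    raise ValueError(f"pair {key} appears with both labels")
                continue
            seen[key] = y
            canon.append((*key, y))
        self.pairs = canon

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str, int]]:
        return iter(self.pairs)

    @property
    def labels(self) -> list[int]:
        return [y for _, _, y in self.pairs]

    def pair_keys(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.pairs}

    def subset(self, indices: Iterable[int]) -> "PairDataset":
        idx = list(indices)
        return PairDataset([self.pairs[i] for i in idx], provenance=self.provenance)

    def validate_against(self, records: ProteinCollection) -> None:
        """Every id must resolve against the record collection."""
        missing = sorted(
            {pid for a, b, _ in self.pairs for pid in (a, b) if pid not in records}
        )
        if missing:
            raise KeyError(f"pair ids not found in protein collection: {missing}")

    def __add__(self, other: "PairDataset") -> "PairDataset":
        return PairDataset(
            self.pairs + other.pairs,
            provenance="; ".join(p for p in (self.provenance, other.provenance) if p),
        )
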