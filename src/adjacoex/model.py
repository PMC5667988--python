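"""Shared genomic data model.

All coordinates are 0-based, half-open ``[start, end)`` — the single
convention used throughout the package. GFF3 input (1-based, inclusive)
is converted at the reading boundary, so interval arithmetic such as
``length = end - start`` is unambiguous everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class ParseError(ValueError):
    """Raised when a file does not parse under the declared dialect."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start: {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"end < start: [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    interval: GenomicInterval
    cytoband: str = ""

    @property
    def tss(self) -> int:
        """Transcription start site: interval start on '+', interval end on '-'.

        Unstranded genes have no defined TSS.
        """
        if self.interval.strand == "+":
            return self.interval.start
        if self.interval.strand == "-":
            return self.interval.end
        raise ValidationError(f"gene {self.gene_id} is unstranded; TSS undefined")


class GeneAnnotation:
    """An ordered, unique-id collection of gene records.

    Records are kept sorted by ``(chrom, start)``; lookups by gene id are
    O(1).
    """

    def __init__(self, records: Iterable[GeneRecord]):
        recs = sorted(records, key=lambda r: (r.interval.chrom, r.interval.start))
        seen: dict[str, GeneRecord] = {}
        for r in recs:
            if r.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {r.gene_id!r}")
            seen[r.gene_id] = r
        self._records: list[GeneRecord] = recs
        self._by_id = seen

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in annotation") from None

    @property
    def records(self) -> list[GeneRecord]:
        return list(self._records)

    def gene_ids(self) -> list[str]:
        """Gene ids in coordinate order."""
        return [r.gene_id for r in self._records]

    def with_cytobands(self, bands: Mapping[str, str]) -> "GeneAnnotation":
        """Return a copy with cytoband labels replaced from a gene_id map."""
        return GeneAnnotation(
            replace(r, cytoband=bands.get(r.gene_id, r.cytoband))
            for r in self._records
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self._records],
                "symbol": [r.symbol for r in self._records],
                "chrom": [r.interval.chrom for r in self._records],
                "start": [r.interval.start for r in self._records],
                "end": [r.interval.end for r in self._records],
                "strand": [r.interval.strand for r in self._records],
                "cytoband": [r.cytoband for r in self._records],
            }
        )


class CytobandMap:
    """Named cytogenetic bands partitioning chromosome arms.

    Bands on the same chromosome must not overlap. Point queries return
    the unique band covering a coordinate.
    """

    def __init__(self, bands: Iterable[tuple[str, GenomicInterval]]):
        self._bands = sorted(bands, key=lambda b: (b[1].chrom, b[1].start))
        by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
        for name, iv in self._bands:
            by_chrom.setdefault(iv.chrom, []).append((name, iv))
        for chrom, blist in by_chrom.items():
            for (_, a), (_, b) in zip(blist, blist[1:]):
                if a.end > b.start:
                    raise ValidationError(
                        f"overlapping bands on {chrom}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )
        self._by_chrom = by_chrom

    def __len__(self) -> int:
        return len(self._bands)

    def __iter__(self) -> Iterator[tuple[str, GenomicInterval]]:
        return iter(self._bands)

    def band_at(self, chrom: str, pos: int) -> str | None:
        blist = self._by_chrom.get(chrom, [])
        starts = [iv.start for _, iv in blist]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and blist[i][1].contains(chrom, pos):
            return blist[i][0]
        return None

    def names(self) -> list[str]:
        return [name for name, _ in self._bands]


class OmicsMatrix:
    """A genes-or-regulators x samples numeric matrix.

    Thin wrapper over a float ``pandas.DataFrame``; missing values are
    ``NaN`` and are carried explicitly (pairwise-deleted downstream,
    never imputed).
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate row ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        self.data = data.astype(float)

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __contains__(self, row_id: str) -> bool:
        return row_id in self.data.index

    def row(self, row_id: str) -> np.ndarray:
        if row_id not in self.data.index:
            raise KeyError(f"row {row_id!r} not in matrix")
        return self.data.loc[row_id].to_numpy()

    def n_nonmissing(self, row_id: str) -> int:
        return int(self.data.loc[row_id].notna().sum())

    def align_columns(self, other: "OmicsMatrix") -> tuple["OmicsMatrix", "OmicsMatrix"]:
        """Restrict both matrices to their shared samples, in common order."""
        shared = [c for c in self.col_ids if c in set(other.col_ids)]
        if not shared:
            raise ValidationError("no shared sample ids between matrices")
        return OmicsMatrix(self.data[shared]), OmicsMatrix(other.data[shared])


class RegulatorSetCollection:
    """Target-gene sets keyed by (regulator, evidence source)."""

    def __init__(self, entries: Mapping[tuple[str, str], Iterable[str]] | None = None):
        self._entries: dict[tuple[str, str], frozenset[str]] = {}
        if entries:
            for key, members in entries.items():
                self.add(key[0], key[1], members)

    def add(self, regulator: str, source: str, members: Iterable[str]) -> None:
        mset = frozenset(members)
        if not mset:
            raise ValidationError(
                f"empty target set for regulator {regulator!r} (source {source!r})"
            )
        key = (regulator, source)
        if key in self._entries:
            self._entries[key] = self._entries[key] | mset
        else:
            self._entries[key] = mset

    def get(self, regulator: str, source: str) -> frozenset[str]:
        try:
            return self._entries[(regulator, source)]
        except KeyError:
            raise KeyError(
                f"no target set for regulator {regulator!r} in source {source!r}"
            ) from None

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[tuple[tuple[str, str], frozenset[str]]]:
        return iter(self._entries.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatorSetCollection):
            return NotImplemented
        return self._entries == other._entries

    def sources(self) -> list[str]:
        return sorted({src for _, src in self._entries})

    def regulators(self, source: str | None = None) -> list[str]:
        return sorted(
            {reg for reg, src in self._entries if source is None or src == source}
        )

    def subset_source(self, source: str) -> "RegulatorSetCollection":
        if source not in self.sources():
            raise KeyError(f"unknown source {source!r}")
        return RegulatorSetCollection(
            {k: v for k, v in self._entries.items() if k[1] == source}
        )
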