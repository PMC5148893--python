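"""Core domain containers: labelled barcode sequences and alignments.

Sequences are uppercase strings over the alphabet ``{A, C, G, T, N, -}``.
``N`` marks an ambiguous base (excluded from training data by the dataset
filters but permitted in query sequences); ``-`` is an alignment gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

VALID_CHARS = frozenset("ACGTN-")
NUCLEOTIDES = "ACGT"


class BarcodeError(ValueError):
    """Raised for malformed barcode data (bad alphabet, ragged alignment...)."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One labelled DNA-barcode sequence.

    Parameters
    ----------
    id :
        Unique sequence identifier (typically a GenBank accession).
    genus, species :
        Taxonomic labels; ``species`` is the full binomial whose first
        token equals ``genus``. Both may be empty for unlabelled records.
    locus :
        Marker locus name, e.g. ``"matK"`` or ``"rbcL"``; ``"other"`` or
        empty when unknown.
    seq :
        Uppercase DNA string over ``{A,C,G,T,N,-}``.
    """

    id: str
    genus: str = ""
    species: str = ""
    locus: str = ""
    seq: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise BarcodeError("record id must be non-empty")
        if not self.seq:
            raise BarcodeError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.seq) - VALID_CHARS
        if bad:
            raise BarcodeError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(allowed: A, C, G, T, N, -)"
            )
        if self.species and self.genus and self.species.split()[0] != self.genus:
            raise BarcodeError(
                f"record {self.id!r}: species {self.species!r} does not start "
                f"with genus {self.genus!r}"
            )

    @property
    def ungapped(self) -> str:
        """Sequence with alignment gaps removed."""
        return self.seq.replace("-", "")

    def with_seq(self, seq: str) -> "BarcodeRecord":
        return replace(self, seq=seq)


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length (aligned) barcode records.

    Attributes
    ----------
    records :
        The aligned sequences, order-preserving.
    column_map :
        Optional map from current 1-based column index to the 1-based
        column index in the original (pre-trimming) alignment. Identity
        when the alignment has never been trimmed.
    """

    records: tuple[BarcodeRecord, ...]
    column_map: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.records:
            raise BarcodeError("alignment must contain at least one record")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) > 1:
            offenders = sorted({r.id for r in self.records})
            raise BarcodeError(
                f"ragged alignment: unequal sequence lengths {sorted(lengths)} "
                f"among records {offenders}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise BarcodeError(f"duplicate record ids in alignment: {dupes}")
        if not self.column_map:
            object.__setattr__(self, "column_map", tuple(range(1, self.c + 1)))
        elif len(self.column_map) != self.c:
            raise BarcodeError("column_map length must equal alignment length")

    @property
    def c(self) -> int:
        """Alignment length in columns."""
        return len(self.records[0].seq)

    @property
    def n(self) -> int:
        """Number of aligned sequences."""
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def column(self, j: int) -> str:
        """Characters of 1-based column ``j``, in record order."""
        if not 1 <= j <= self.c:
            raise IndexError(f"column {j} out of range 1..{self.c}")
        return "".join(r.seq[j - 1] for r in self.records)

    def subset(self, predicate) -> "Alignment":
        """New alignment keeping records for which ``predicate(record)``."""
        kept = tuple(r for r in self.records if predicate(r))
        if not kept:
            raise BarcodeError("subset would produce an empty alignment")
        return Alignment(records=kept, column_map=self.column_map)
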