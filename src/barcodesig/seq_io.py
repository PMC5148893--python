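"""FASTA / taxonomy input-output and dataset inclusion filters.

The taxonomy sidecar is a TSV with columns ``id  genus  species  locus``
and always overrides whatever can be parsed from FASTA headers. Without
it, headers are assumed to follow the GenBank deposit convention
``>ACCESSION Genus species ...`` (tokens 2-3 are the binomial).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .records import Alignment, BarcodeRecord, BarcodeError

log = logging.getLogger(__name__)

KNOWN_LOCI = ("matK", "rbcL")


def read_taxonomy(path: str | Path) -> dict[str, tuple[str, str, str]]:
    """Read a taxonomy TSV ``id<TAB>genus<TAB>species<TAB>locus``."""
    table: dict[str, tuple[str, str, str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise BarcodeError(
                f"{path}:{lineno}: expected 4 tab-separated fields "
                f"(id, genus, species, locus), got {len(parts)}"
            )
        table[parts[0]] = (parts[1], parts[2], parts[3])
    return table


def _parse_header(description: str) -> tuple[str, str]:
    """Extract (genus, species-binomial) from a GenBank-style header."""
    tokens = description.split()
    if len(tokens) >= 3 and tokens[1][:1].isupper() and tokens[2].islower():
        return tokens[1], f"{tokens[1]} {tokens[2]}"
    return "", ""


def read_fasta(
    path: str | Path,
    taxonomy: str | Path | None = None,
    locus: str = "",
) -> list[BarcodeRecord]:
    """Read barcode records from FASTA, labelling them with taxonomy.

    Labels come from the ``taxonomy`` TSV when given (ids absent from the
    TSV trigger a warning and stay unlabelled); otherwise genus/species
    are parsed from the header. Sequences are upper-cased. Duplicate ids
    and characters outside ``{A,C,G,T,N,-}`` are errors.
    """
    taxmap = read_taxonomy(taxonomy) if taxonomy is not None else None
    records: list[BarcodeRecord] = []
    seen: set[str] = set()
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        warnings.warn(f"{path}: no FASTA entries found", stacklevel=2)
    for entry in entries:
        rid = entry.id
        if rid in seen:
            raise BarcodeError(f"{path}: duplicate sequence id {rid!r}")
        seen.add(rid)
        if taxmap is not None:
            if rid in taxmap:
                genus, species, loc = taxmap[rid]
            else:
                warnings.warn(
                    f"{path}: id {rid!r} not in taxonomy file; record kept unlabelled",
                    stacklevel=2,
                )
                genus, species, loc = "", "", ""
        else:
            genus, species = _parse_header(entry.description)
            loc = locus
        records.append(
            BarcodeRecord(
                id=rid, genus=genus, species=species, locus=loc or locus,
                seq=str(entry.seq).upper(),
            )
        )
    return records


def write_fasta(records: list[BarcodeRecord] | Alignment, path: str | Path) -> None:
    """Write records to FASTA (60-column wrap), one entry per record."""
    if isinstance(records, Alignment):
        records = list(records.records)
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), 60):
                fh.write(r.seq[i : i + 60] + "\n")


def write_taxonomy(records: list[BarcodeRecord] | Alignment, path: str | Path) -> None:
    if isinstance(records, Alignment):
        records = list(records.records)
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.id}\t{r.genus}\t{r.species}\t{r.locus}\n")


@dataclass
class FilterCounts:
    """Per-rule tallies from :func:`filter_dataset`."""

    input: int = 0
    wrong_locus: int = 0
    contains_n: int = 0
    too_few_per_species: int = 0
    kept: int = 0


def filter_dataset(
    records: list[BarcodeRecord],
    locus: str = "matK",
    counts: FilterCounts | None = None,
) -> list[BarcodeRecord]:
    """Apply the dataset-inclusion filters for signature training data.

    Keeps records of the requested locus, removes any sequence containing
    ``N``, then removes species left with fewer than two sequences. The
    N-removal happens before the per-species count, so a species whose
    only clean sequence survives is still excluded. Idempotent.
    """
    counts = counts if counts is not None else FilterCounts()
    counts.input = len(records)
    at_locus = [r for r in records if r.locus == locus]
    counts.wrong_locus = len(records) - len(at_locus)
    clean = [r for r in at_locus if "N" not in r.seq]
    counts.contains_n = len(at_locus) - len(clean)
    per_species: dict[str, int] = {}
    for r in clean:
        per_species[r.species] = per_species.get(r.species, 0) + 1
    kept = [r for r in clean if per_species[r.species] >= 2]
    counts.too_few_per_species = len(clean) - len(kept)
    counts.kept = len(kept)
    if not kept:
        warnings.warn("filter_dataset: no records survived filtering", stacklevel=2)
    log.info(
        "filter_dataset: %d in, %d wrong locus, %d with N, %d in rare species, %d kept",
        counts.input, counts.wrong_locus, counts.contains_n,
        counts.too_few_per_species, counts.kept,
    )
    return kept


def read_alignment(path: str | Path, taxonomy: str | Path | None = None) -> Alignment:
    """Read an aligned FASTA file; all entries must have equal length."""
    records = read_fasta(path, taxonomy=taxonomy)
    if not records:
        raise BarcodeError(f"{path}: empty alignment file")
    return Alignment(records=tuple(records))


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment to FASTA; round-trips through read_alignment."""
    write_fasta(alignment, path)
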