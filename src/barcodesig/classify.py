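"""Signature search against query sequences and result summaries.

Search is forward-strand only (barcode amplicons are deposited in a
canonical orientation); pass ``both_strands=True`` to also test the
reverse complement of each query. ``N`` in a query never matches a
pattern literal. Each query is reported at most once per signature,
at the leftmost occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import BarcodeError, BarcodeRecord
from .signatures import Signature

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    query_length: int
    matched_species: str | None
    match_start: int | None  # 1-based inclusive
    match_end: int | None
    signature_used: str = ""
    ambiguous: bool = False

    @property
    def identified(self) -> bool:
        return self.matched_species is not None and not self.ambiguous


def search_signature(
    sig: Signature,
    queries: list[BarcodeRecord],
    both_strands: bool = False,
) -> list[ClassificationResult]:
    """Match one signature against each query; leftmost hit wins."""
    results = []
    for q in queries:
        seq = q.ungapped
        m = sig.search(seq)
        if m is None and both_strands:
            m = sig.search(reverse_complement(seq))
        if m is not None:
            results.append(
                ClassificationResult(
                    query_id=q.id,
                    query_length=len(seq),
                    matched_species=sig.species,
                    match_start=m.start() + 1,
                    match_end=m.end(),
                    signature_used=sig.species,
                )
            )
        else:
            results.append(
                ClassificationResult(
                    query_id=q.id,
                    query_length=len(seq),
                    matched_species=None,
                    match_start=None,
                    match_end=None,
                )
            )
    return results


def classify(
    signatures: list[Signature],
    queries: list[BarcodeRecord],
    both_strands: bool = False,
) -> list[ClassificationResult]:
    """Assign each query the species of the signature(s) it matches.

    Exactly one matching signature assigns that species; none leaves
    the query unidentified; two or more flag it ambiguous, with all
    matching species semicolon-joined in ``signature_used``.
    """
    species = [s.species for s in signatures]
    if len(set(species)) != len(species):
        dupes = sorted({sp for sp in species if species.count(sp) > 1})
        raise BarcodeError(f"duplicate species among signatures: {dupes}")
    results = []
    for q in queries:
        seq = q.ungapped
        hits: list[tuple[Signature, int, int]] = []
        for sig in signatures:
            m = sig.search(seq)
            if m is None and both_strands:
                m = sig.search(reverse_complement(seq))
            if m is not None:
                hits.append((sig, m.start() + 1, m.end()))
        if not hits:
            results.append(
                ClassificationResult(q.id, len(seq), None, None, None)
            )
        elif len(hits) == 1:
            sig, start, end = hits[0]
            results.append(
                ClassificationResult(
                    q.id, len(seq), sig.species, start, end, sig.species
                )
            )
        else:
            sig, start, end = hits[0]
            results.append(
                ClassificationResult(
                    query_id=q.id,
                    query_length=len(seq),
                    matched_species=hits[0][0].species,
                    match_start=start,
                    match_end=end,
                    signature_used=";".join(h[0].species for h in hits),
                    ambiguous=True,
                )
            )
    return results


@dataclass
class ClassificationSummary:
    n_identified: int
    n_unidentified: int
    n_ambiguous: int
    per_species: dict[str, int]

    @property
    def total(self) -> int:
        return self.n_identified + self.n_unidentified + self.n_ambiguous


def summarize(results: list[ClassificationResult]) -> ClassificationSummary:
    """Tally identified / unidentified / ambiguous queries per species."""
    n_id = sum(1 for r in results if r.identified)
    n_amb = sum(1 for r in results if r.ambiguous)
    n_un = len(results) - n_id - n_amb
    per_species: dict[str, int] = {}
    for r in results:
        if r.identified:
            assert r.matched_species is not None
            per_species[r.matched_species] = per_species.get(r.matched_species, 0) + 1
    return ClassificationSummary(
        n_identified=n_id,
        n_unidentified=n_un,
        n_ambiguous=n_amb,
        per_species=per_species,
    )


def write_results_tsv(results: list[ClassificationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tlength\tmatched_species\tmatch_start\tmatch_end\tambiguous\n")
        for r in results:
            fh.write(
                f"{r.query_id}\t{r.query_length}\t{r.matched_species or '-'}\t"
                f"{r.match_start or '-'}\t{r.match_end or '-'}\t{int(r.ambiguous)}\n"
            )
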