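"""Position frequency/probability matrices, gap trimming and consensus.

The position probability matrix entry for nucleotide ``k`` at column
``j`` is the fraction of the ``N`` aligned sequences carrying ``k``
there:

    M[k, j] = (1/N) * sum_i I(X[i, j] == k)

Rows are in fixed order A, C, G, T everywhere in this package. Gaps
contribute no count and probabilities are deliberately NOT renormalised,
so a column retaining gaps has probability mass below 1 — gap regions
are expected to be trimmed before PSSM work, and residual gaps should
stay visible rather than be hidden by renormalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import Alignment, BarcodeError, NUCLEOTIDES

#: fixed nucleotide row order for all PFM/PPM arrays
ROW_ORDER = NUCLEOTIDES  # "ACGT"
_ROW_INDEX = {b: i for i, b in enumerate(ROW_ORDER)}


@dataclass
class PSSMMatrix:
    """Per-column nucleotide counts and probabilities for an alignment.

    ``counts[k, j]`` is the number of sequences with nucleotide
    ``ROW_ORDER[k]`` at 0-based column ``j``; ``probs = counts / N``.
    """

    counts: np.ndarray  # (4, c) int
    n: int
    probs: np.ndarray | None = None

    @property
    def c(self) -> int:
        return self.counts.shape[1]

    def to_tsv(self, path: str | Path, which: str = "counts") -> None:
        """Write the matrix as TSV: one row per nucleotide, columns 1..c."""
        mat = self.counts if which == "counts" else self.probs
        if mat is None:
            raise BarcodeError("probabilities not computed yet; call compute_ppm")
        with open(path, "w") as fh:
            fh.write("base\t" + "\t".join(str(j + 1) for j in range(self.c)) + "\n")
            for i, base in enumerate(ROW_ORDER):
                cells = (
                    "\t".join(str(int(x)) for x in mat[i])
                    if which == "counts"
                    else "\t".join(format(float(x), ".10g") for x in mat[i])
                )
                fh.write(f"{base}\t{cells}\n")


@dataclass(frozen=True)
class ConsensusSeq:
    """Majority-base consensus of an alignment, with tie bookkeeping."""

    group: str
    seq: str
    tie_columns: tuple[int, ...] = field(default=())  # 1-based


def _char_matrix(alignment: Alignment) -> np.ndarray:
    return np.array([list(r.seq) for r in alignment.records], dtype="U1")


def trim_gap_columns(alignment: Alignment, max_gap_frac: float = 0.0) -> Alignment:
    """Drop columns whose gap fraction exceeds ``max_gap_frac``.

    The default 0.0 removes every column containing a gap, producing the
    equal-length gap-free alignment the downstream matrices assume. The
    returned alignment's ``column_map`` gives, for each surviving column,
    its 1-based coordinate in the input alignment (composed with any
    earlier trims), so sites can be reported in original coordinates.
    """
    if not 0.0 <= max_gap_frac <= 1.0:
        raise BarcodeError("max_gap_frac must be in [0, 1]")
    chars = _char_matrix(alignment)
    gap_frac = (chars == "-").mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_frac)
    if keep.size == 0:
        raise BarcodeError("trim_gap_columns would remove every column")
    new_records = tuple(
        r.with_seq("".join(np.asarray(list(r.seq))[keep]))
        for r in alignment.records
    )
    new_map = tuple(alignment.column_map[j] for j in keep)
    return Alignment(records=new_records, column_map=new_map)


def compute_pfm(alignment: Alignment) -> PSSMMatrix:
    """Count each nucleotide's occurrences per column (gaps uncounted)."""
    chars = _char_matrix(alignment)
    counts = np.zeros((4, alignment.c), dtype=np.int64)
    for i, base in enumerate(ROW_ORDER):
        counts[i] = (chars == base).sum(axis=0)
    return PSSMMatrix(counts=counts, n=alignment.n)


def compute_ppm(pfm: PSSMMatrix) -> PSSMMatrix:
    """Fill probabilities probs = counts / N.

    On gap-free columns every column sums to exactly 1; columns with
    residual gaps (or N's) sum to less than 1 by design.
    """
    if pfm.n <= 0:
        raise BarcodeError("cannot normalise a PFM with N = 0 sequences")
    pfm.probs = pfm.counts / float(pfm.n)
    return pfm


def pssm(alignment: Alignment) -> PSSMMatrix:
    """Convenience: PFM + PPM in one call."""
    return compute_ppm(compute_pfm(alignment))


def consensus(alignment: Alignment, group: str = "") -> ConsensusSeq:
    """Per-column majority base over A/C/G/T.

    Ties are broken toward the alphabetically first base and the column
    recorded in ``tie_columns`` (1-based, current coordinates), keeping
    the consensus in the plain 4-letter alphabet. A column containing
    only gaps has no majority base and is an error — trim first.
    """
    counts = compute_pfm(alignment).counts
    col_tot = counts.max(axis=0)
    if (col_tot == 0).any():
        bad = [int(j) + 1 for j in np.flatnonzero(col_tot == 0)]
        raise BarcodeError(
            f"all-gap column(s) {bad}: run trim_gap_columns before consensus"
        )
    best = counts.argmax(axis=0)  # argmax takes the first max -> A<C<G<T order
    ties = tuple(
        int(j) + 1
        for j in range(counts.shape[1])
        if (counts[:, j] == counts[best[j], j]).sum() > 1
    )
    seq = "".join(ROW_ORDER[k] for k in best)
    return ConsensusSeq(group=group, seq=seq, tie_columns=ties)
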