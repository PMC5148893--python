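"""Species discrimination from PSSM probability vectors.

Each aligned sequence is mapped to a vector of the column probabilities
of its own bases; Euclidean distances between these vectors give the
pairwise divergence used by the discrimination rule. A species pair is
resolvable (the "barcoding gap") when its smallest between-species
distance both exceeds the largest within-species distance of either
species and is strictly positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import wilcoxon

from .pssm import PSSMMatrix, _ROW_INDEX
from .records import Alignment, BarcodeError


@dataclass(frozen=True)
class SeqProbVector:
    """Per-sequence vector of own-base column probabilities (0 at gaps)."""

    record_id: str
    v: np.ndarray


@dataclass
class DistanceMatrix:
    """Symmetric Euclidean distance matrix over sequence ids."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.d[i, j])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, rid in enumerate(self.ids):
                fh.write(rid + "\t" + "\t".join(format(x, ".10g") for x in self.d[i]) + "\n")


@dataclass(frozen=True)
class PairResult:
    species_a: str
    species_b: str
    min_inter: float
    max_intra_a: float
    max_intra_b: float
    discriminated: bool


@dataclass
class DiscriminationReport:
    """Pairwise and per-species outcomes of the distance rule."""

    pairs: list[PairResult]
    species_table: dict[str, bool] = field(default_factory=dict)

    @property
    def n_discriminated(self) -> int:
        return sum(self.species_table.values())

    @property
    def n_not(self) -> int:
        return len(self.species_table) - self.n_discriminated

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("species_a\tspecies_b\tmin_inter\tmax_intra_a\tmax_intra_b\tdiscriminated\n")
            for p in self.pairs:
                fh.write(
                    f"{p.species_a}\t{p.species_b}\t{p.min_inter:.10g}\t"
                    f"{p.max_intra_a:.10g}\t{p.max_intra_b:.10g}\t{int(p.discriminated)}\n"
                )
            fh.write("#species\tdiscriminated_overall\n")
            for sp in sorted(self.species_table):
                fh.write(f"#{sp}\t{int(self.species_table[sp])}\n")


def probability_vectors(alignment: Alignment, matrix: PSSMMatrix) -> list[SeqProbVector]:
    """One probability vector per sequence: v[j] = P(base of seq i at j).

    Gap (and N) positions contribute 0. Requires the matrix to have been
    computed from an alignment of the same length.
    """
    if matrix.probs is None:
        raise BarcodeError("PSSM probabilities missing; call compute_ppm first")
    if matrix.c != alignment.c:
        raise BarcodeError(
            f"alignment length {alignment.c} != PSSM length {matrix.c}"
        )
    out = []
    for rec in alignment.records:
        idx = np.array([_ROW_INDEX.get(ch, -1) for ch in rec.seq])
        v = np.where(idx >= 0, matrix.probs[np.clip(idx, 0, 3), np.arange(matrix.c)], 0.0)
        out.append(SeqProbVector(record_id=rec.id, v=v))
    return out


def pairwise_distances(vectors: list[SeqProbVector]) -> DistanceMatrix:
    """Euclidean distances between all probability vectors."""
    lengths = {len(sv.v) for sv in vectors}
    if len(lengths) > 1:
        raise BarcodeError(f"probability vectors of unequal length: {sorted(lengths)}")
    mat = np.vstack([sv.v for sv in vectors])
    d = squareform(pdist(mat, metric="euclidean")) if len(vectors) > 1 else np.zeros((1, 1))
    return DistanceMatrix(ids=tuple(sv.record_id for sv in vectors), d=d)


def discriminate_species(
    dm: DistanceMatrix,
    labels: dict[str, str],
    pair_policy: str = "all",
) -> DiscriminationReport:
    """Score every unordered species pair with the barcoding-gap rule.

    A pair is discriminated iff ``min_inter > max(max_intra_a,
    max_intra_b)`` and ``min_inter > 0`` (strict inequalities; ties
    fail). Singleton species have no intra pair and get ``max_intra =
    0``, reducing the rule to ``min_inter > 0``.

    ``pair_policy`` controls the per-species tally: a species counts as
    discriminated overall if ``all`` (default, strictest), ``any``, or a
    ``majority`` of its pairs are discriminated.
    """
    if pair_policy not in ("all", "any", "majority"):
        raise BarcodeError(f"unknown pair_policy {pair_policy!r}")
    missing = [rid for rid in dm.ids if rid not in labels]
    if missing:
        raise BarcodeError(f"unlabelled sequence ids: {missing}")
    by_species: dict[str, list[int]] = {}
    for i, rid in enumerate(dm.ids):
        by_species.setdefault(labels[rid], []).append(i)

    def max_intra(idxs: list[int]) -> float:
        if len(idxs) < 2:
            return 0.0
        sub = dm.d[np.ix_(idxs, idxs)]
        return float(sub.max())

    species = sorted(by_species)
    intra = {sp: max_intra(by_species[sp]) for sp in species}
    pairs: list[PairResult] = []
    per_species_hits: dict[str, list[bool]] = {sp: [] for sp in species}
    for a_i, sp_a in enumerate(species):
        for sp_b in species[a_i + 1 :]:
            inter = dm.d[np.ix_(by_species[sp_a], by_species[sp_b])]
            min_inter = float(inter.min())
            ok = min_inter > max(intra[sp_a], intra[sp_b]) and min_inter > 0.0
            pairs.append(
                PairResult(sp_a, sp_b, min_inter, intra[sp_a], intra[sp_b], ok)
            )
            per_species_hits[sp_a].append(ok)
            per_species_hits[sp_b].append(ok)

    def overall(hits: list[bool]) -> bool:
        if not hits:
            return False
        if pair_policy == "all":
            return all(hits)
        if pair_policy == "any":
            return any(hits)
        return sum(hits) * 2 > len(hits)

    table = {sp: overall(per_species_hits[sp]) for sp in species}
    return DiscriminationReport(pairs=pairs, species_table=table)


def compare_loci(divergence_a: list[float], divergence_b: list[float]) -> dict[str, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-pair divergences.

    Used to compare sequence variation between two loci over the same
    species pairs. All-zero differences yield p = 1 by convention.
    """
    if len(divergence_a) != len(divergence_b):
        raise BarcodeError(
            f"paired divergence lists of unequal length: "
            f"{len(divergence_a)} vs {len(divergence_b)}"
        )
    a = np.asarray(divergence_a, dtype=float)
    b = np.asarray(divergence_b, dtype=float)
    if np.all(a == b):
        warnings.warn("compare_loci: all paired differences are zero", stacklevel=2)
        return {"statistic": 0.0, "p": 1.0}
    res = wilcoxon(a, b, alternative="two-sided")
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}
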