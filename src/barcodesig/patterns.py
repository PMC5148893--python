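"""Discovery of discriminating nucleotide sites and literal patterns.

Site discovery is two-step: first among per-genus consensus sequences
(inter-genus variable columns), then within each genus among the
per-species consensus bases (columns fixed within every species but
differing between at least two species). Sites live in alignment-column
coordinates; the patterns assembled around them live in ungapped 1-based
coordinates on a chosen exemplar sequence, with an explicit column-to-
position map bridging the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .pssm import consensus
from .records import Alignment, BarcodeError, BarcodeRecord


@dataclass(frozen=True)
class DiscriminatingSite:
    """One variable alignment column diagnostic at genus or species level.

    ``column`` is 1-based in ORIGINAL alignment coordinates (i.e. after
    applying the alignment's column_map); ``alleles`` maps group name
    (genus or species binomial) to the base observed there.
    """

    column: int
    level: str  # "genus" | "species"
    alleles: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        bases = {b for _, b in self.alleles}
        if len(bases) < 2:
            raise BarcodeError(
                f"site at column {self.column}: needs >=2 distinct bases, got {bases}"
            )

    @property
    def allele_map(self) -> dict[str, str]:
        return dict(self.alleles)


@dataclass(frozen=True)
class Pattern:
    """A literal subsequence anchored on an exemplar's ungapped sequence."""

    start: int  # 1-based position in the ungapped exemplar
    literal: str
    sites_covered: tuple[int, ...] = ()  # original alignment columns

    def __post_init__(self) -> None:
        if self.start < 1:
            raise BarcodeError("pattern start must be >= 1 (1-based)")
        if not self.literal or set(self.literal) - set("ACGT"):
            raise BarcodeError(f"pattern literal must be non-empty ACGT: {self.literal!r}")

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + len(self.literal) - 1


def genus_level_sites(consensuses: list) -> list[DiscriminatingSite]:
    """Variable columns among genus consensus sequences.

    Every column where at least two consensuses disagree becomes a site
    carrying the full per-genus allele map. Consensuses must be aligned
    to a common length; at least two are required.
    """
    if len(consensuses) < 2:
        raise BarcodeError("need >=2 genus consensuses to compare")
    lengths = {len(cs.seq) for cs in consensuses}
    if len(lengths) > 1:
        raise BarcodeError(f"consensus sequences of unequal length: {sorted(lengths)}")
    c = lengths.pop()
    sites = []
    for j in range(c):
        col = {cs.group: cs.seq[j] for cs in consensuses}
        if len(set(col.values())) >= 2:
            sites.append(
                DiscriminatingSite(
                    column=j + 1,
                    level="genus",
                    alleles=tuple(sorted(col.items())),
                )
            )
    return sites


def species_level_sites(
    genus_alignment: Alignment,
    labels: dict[str, str] | None = None,
) -> list[DiscriminatingSite]:
    """Diagnostic columns among the species of one genus.

    A column qualifies when it is fixed (monomorphic over A/C/G/T, no
    gaps) within every species yet differs between at least two species.
    Columns polymorphic inside any species are excluded: a signature
    must match all sequences of its target species, so only
    within-species-fixed differences are usable. Reported columns use
    original alignment coordinates via the alignment's column_map.
    """
    labels = labels or {r.id: r.species for r in genus_alignment.records}
    by_species: dict[str, list[BarcodeRecord]] = {}
    for rec in genus_alignment.records:
        sp = labels.get(rec.id, rec.species)
        by_species.setdefault(sp, []).append(rec)
    if len(by_species) < 2:
        raise BarcodeError("need >=2 species within the genus to compare")
    sites = []
    species = sorted(by_species)
    for j in range(genus_alignment.c):
        fixed: dict[str, str] = {}
        ok = True
        for sp in species:
            bases = {r.seq[j] for r in by_species[sp]}
            if len(bases) != 1 or bases & {"-", "N"}:
                ok = False
                break
            fixed[sp] = bases.pop()
        if ok and len(set(fixed.values())) >= 2:
            sites.append(
                DiscriminatingSite(
                    column=genus_alignment.column_map[j],
                    level="species",
                    alleles=tuple(sorted(fixed.items())),
                )
            )
    return sites


def dedupe_sites(*site_lists: list[DiscriminatingSite]) -> list[DiscriminatingSite]:
    """Concatenate site lists, keeping the first site seen per column.

    Genus- and species-level sites are combined for signature
    generation; a column found at both levels is kept once (species
    level first if passed first).
    """
    seen: set[int] = set()
    out = []
    for sites in site_lists:
        for s in sites:
            if s.column not in seen:
                seen.add(s.column)
                out.append(s)
    return sorted(out, key=lambda s: s.column)


def column_to_ungapped(aligned_seq: str) -> dict[int, int]:
    """Map original 1-based alignment column -> 1-based ungapped position.

    Columns where the sequence has a gap are absent from the map.
    """
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(aligned_seq, start=1):
        if ch != "-":
            pos += 1
            mapping[col] = pos
    return mapping


def build_patterns(
    sites: list[DiscriminatingSite],
    target: BarcodeRecord,
    aligned_target: str,
    flank: int = 6,
    column_map: tuple[int, ...] | None = None,
) -> list[Pattern]:
    """Expand sites into flanked literal windows on the target sequence.

    Each site's alignment column is mapped to an ungapped position of
    ``target`` (a site falling in one of the target's gaps is skipped
    with a warning), then widened by ``flank`` bases on each side,
    clipped to the sequence bounds. Overlapping or book-ended windows
    merge into one pattern. Literals are read off the target's ungapped
    sequence, so every pattern matches its exemplar by construction.

    ``aligned_target`` is the target's row in the ORIGINAL (untrimmed)
    alignment. If the sites were produced from a trimmed alignment their
    columns are already in original coordinates; ``column_map`` is only
    needed when site columns are in some other (current) coordinate
    system and must be translated first.
    """
    if flank < 0:
        raise BarcodeError("flank must be >= 0")
    ungapped = target.seq.replace("-", "")
    col2pos = column_to_ungapped(aligned_target)
    windows: list[tuple[int, int, int]] = []  # (lo, hi, column) in ungapped coords
    for site in sites:
        col = site.column if column_map is None else column_map[site.column - 1]
        pos = col2pos.get(col)
        if pos is None:
            warnings.warn(
                f"site at alignment column {col} falls in a gap of {target.id}; skipped",
                stacklevel=2,
            )
            continue
        lo = max(1, pos - flank)
        hi = min(len(ungapped), pos + flank)
        windows.append((lo, hi, col))
    if not windows:
        return []
    windows.sort()
    merged: list[list] = []  # [lo, hi, [cols]]
    for lo, hi, col in windows:
        if merged and lo <= merged[-1][1] + 1:  # overlap or adjacency
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][2].append(col)
        else:
            merged.append([lo, hi, [col]])
    return [
        Pattern(
            start=lo,
            literal=ungapped[lo - 1 : hi],
            sites_covered=tuple(sorted(cols)),
        )
        for lo, hi, cols in merged
    ]


def write_sites_tsv(sites: list[DiscriminatingSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tlevel\tgroup\tallele\n")
        for s in sites:
            for group, base in s.alleles:
                fh.write(f"{s.column}\t{s.level}\t{group}\t{base}\n")
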