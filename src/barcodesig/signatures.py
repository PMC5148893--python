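"""Regex species signatures: assembly, refinement, evaluation, selection.

A signature is an ordered series of literal patterns joined by exact
inter-pattern distances, serialised as a regular expression such as::

    GTCTTGGAATAGG.{77}TTCTCATGT...

The distances are exact by default (``.{d}``): signature failures on
real data are typically caused by indels shifting pattern spacing, and a
fixed repetition makes that failure mode explicit. An optional symmetric
tolerance ``t`` relaxes each distance to ``.{d-t,d+t}``.

Evaluation is per sequence: TP = target-species sequences matched,
FN = target sequences missed, FP = other-species sequences matched;
recall = TP/(TP+FN), precision = TP/(TP+FP), F = 2PR/(P+R) (balanced
F1), binned into categories A [0.75,1], B [0.50,0.75), C [0.25,0.50),
D [0,0.25).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace

from .patterns import DiscriminatingSite, Pattern
from .records import BarcodeError, BarcodeRecord

_SIG_RE = re.compile(r"([ACGT]+)|\.\{(\d+)(?:,(\d+))?\}")


@dataclass(frozen=True)
class Signature:
    """An ordered pattern series with exact inter-pattern distances."""

    species: str
    patterns: tuple[Pattern, ...]
    exemplar_id: str = ""
    tolerance: int = 0

    def __post_init__(self) -> None:
        if not self.patterns:
            raise BarcodeError("signature needs at least one pattern")
        for prev, cur in zip(self.patterns, self.patterns[1:]):
            if cur.start <= prev.end:
                raise BarcodeError(
                    f"overlapping patterns at {prev.start} and {cur.start}"
                )

    @property
    def gaps(self) -> tuple[int, ...]:
        """gaps[i] = bases strictly between pattern i and pattern i+1."""
        return tuple(
            cur.start - prev.end - 1
            for prev, cur in zip(self.patterns, self.patterns[1:])
        )

    @property
    def span(self) -> tuple[int, int, int]:
        """(start, end, length), 1-based inclusive on the exemplar."""
        start = self.patterns[0].start
        end = self.patterns[-1].end
        return (start, end, end - start + 1)

    @property
    def regex(self) -> str:
        parts = [self.patterns[0].literal]
        for gap, pat in zip(self.gaps, self.patterns[1:]):
            if self.tolerance > 0:
                lo = max(0, gap - self.tolerance)
                parts.append(f".{{{lo},{gap + self.tolerance}}}")
            else:
                parts.append(f".{{{gap}}}")
            parts.append(pat.literal)
        return "".join(parts)

    def compiled(self) -> re.Pattern:
        return re.compile(self.regex)

    def search(self, seq: str) -> re.Match | None:
        """Leftmost match of the signature in an ungapped query sequence.

        ``N`` never matches a literal (literals are pure ACGT); bases in
        the inter-pattern runs are unconstrained.
        """
        return self.compiled().search(seq)


def assemble_signature(
    species: str,
    patterns: list[Pattern],
    exemplar_id: str = "",
    tolerance: int = 0,
) -> Signature:
    """Build a signature from patterns; sorts them (with a warning) if needed."""
    pats = list(patterns)
    if pats != sorted(pats, key=lambda p: p.start):
        warnings.warn("patterns were not sorted by start; sorting", stacklevel=2)
        pats = sorted(pats, key=lambda p: p.start)
    return Signature(
        species=species,
        patterns=tuple(pats),
        exemplar_id=exemplar_id,
        tolerance=tolerance,
    )


def serialize_signature(sig: Signature) -> str:
    """Two-line text form (also the QR payload body, byte for byte)."""
    start, end, _ = sig.span
    header = f"#species={sig.species}\t#exemplar={sig.exemplar_id}\t#span={start}-{end}"
    return f"{header}\n{sig.regex}\n"


def parse_signature(text: str) -> Signature:
    """Inverse of :func:`serialize_signature` (round-trips exactly)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) != 2 or not lines[0].startswith("#species="):
        raise BarcodeError("signature text must be a '#species=...' header plus a regex line")
    fields = dict(
        item.lstrip("#").split("=", 1) for item in lines[0].split("\t") if "=" in item
    )
    species = fields.get("species", "")
    exemplar = fields.get("exemplar", "")
    span_start = int(fields["span"].split("-")[0]) if "span" in fields else 1
    pos = span_start
    patterns: list[Pattern] = []
    tolerance = 0
    consumed = 0
    for m in _SIG_RE.finditer(lines[1]):
        if m.start() != consumed:
            raise BarcodeError(f"unparseable signature regex near offset {consumed}")
        consumed = m.end()
        if m.group(1):
            patterns.append(Pattern(start=pos, literal=m.group(1)))
            pos += len(m.group(1))
        else:
            lo = int(m.group(2))
            hi = int(m.group(3)) if m.group(3) is not None else lo
            tolerance = max(tolerance, (hi - lo + 1) // 2)
            pos += (lo + hi) // 2
    if consumed != len(lines[1]):
        raise BarcodeError(f"unparseable signature regex near offset {consumed}")
    return Signature(
        species=species,
        patterns=tuple(patterns),
        exemplar_id=exemplar,
        tolerance=tolerance,
    )


@dataclass(frozen=True)
class EvaluationReport:
    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def category(self) -> str:
        return categorize(self.f_measure)


def categorize(f: float) -> str:
    """Bin an F-measure into the A-D performance categories.

    Intervals are closed on the left: A [0.75, 1], B [0.50, 0.75),
    C [0.25, 0.50), D [0, 0.25).
    """
    if not 0.0 <= f <= 1.0:
        raise BarcodeError(f"F-measure {f} outside [0, 1]")
    if f >= 0.75:
        return "A"
    if f >= 0.50:
        return "B"
    if f >= 0.25:
        return "C"
    return "D"


def _seq_of(item) -> str:
    return item.ungapped if isinstance(item, BarcodeRecord) else str(item).replace("-", "")


def evaluate_signature(
    sig: Signature,
    target_seqs: list,
    other_seqs: list,
) -> EvaluationReport:
    """Count per-sequence hits of the signature in both datasets.

    A sequence counts at most once however many times the signature
    occurs in it. Inputs may be records (degapped automatically) or
    plain strings.
    """
    tp = sum(1 for s in target_seqs if sig.search(_seq_of(s)) is not None)
    fn = len(target_seqs) - tp
    fp = sum(1 for s in other_seqs if sig.search(_seq_of(s)) is not None)
    return EvaluationReport(tp=tp, fp=fp, fn=fn)


def incorporate_site(
    sig: Signature,
    site: DiscriminatingSite,
    target: BarcodeRecord,
    aligned_target: str,
    flank: int = 6,
) -> Signature | None:
    """Add one site's flanked window to a signature's pattern series.

    The window merges with overlapping or book-ended existing patterns
    (extending them) or becomes a new pattern; literals are re-read from
    the exemplar's ungapped sequence. Returns None when the site falls
    in a gap of the exemplar.
    """
    from .patterns import column_to_ungapped  # local to avoid cycle

    ungapped = target.seq.replace("-", "")
    pos = column_to_ungapped(aligned_target).get(site.column)
    if pos is None:
        return None
    lo = max(1, pos - flank)
    hi = min(len(ungapped), pos + flank)
    intervals = [(p.start, p.end, set(p.sites_covered)) for p in sig.patterns]
    intervals.append((lo, hi, {site.column}))
    intervals.sort(key=lambda t: t[0])
    merged: list[list] = []
    for a, b, cols in intervals:
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
            merged[-1][2] |= cols
        else:
            merged.append([a, b, set(cols)])
    pats = tuple(
        Pattern(start=a, literal=ungapped[a - 1 : b], sites_covered=tuple(sorted(cols)))
        for a, b, cols in merged
    )
    return replace(sig, patterns=pats)


def refine_signature(
    sig: Signature,
    target_seqs: list,
    other_seqs: list,
    site_pool: list[DiscriminatingSite],
    target: BarcodeRecord,
    aligned_target: str,
    flank: int = 6,
) -> tuple[Signature, list[Signature]]:
    """Greedily add discriminating sites until false positives vanish.

    While the signature still matches other-species sequences and
    unused sites remain, the site whose incorporation (via
    :func:`incorporate_site`) most reduces FP — without reducing TP —
    is added. Returns the refined signature and the trajectory
    [input, after 1 addition, ...]; the final signature may still have
    FP > 0 if no site helps, in which case a warning flags it.
    """
    used_cols = {c for p in sig.patterns for c in p.sites_covered}
    pool = [s for s in site_pool if s.column not in used_cols]
    trajectory = [sig]
    current = sig
    report = evaluate_signature(current, target_seqs, other_seqs)
    while report.fp > 0 and pool:
        best: tuple[tuple[int, int], Signature, DiscriminatingSite] | None = None
        for cand in pool:
            trial = incorporate_site(current, cand, target, aligned_target, flank)
            if trial is None:
                continue
            r = evaluate_signature(trial, target_seqs, other_seqs)
            if r.tp < report.tp:
                continue
            key = (r.fp, -r.tp)
            if best is None or key < best[0]:
                best = (key, trial, cand)
        if best is None or best[0][0] >= report.fp:
            warnings.warn(
                f"refine_signature({sig.species}): {report.fp} false positives "
                "remain and no unused site reduces them",
                stacklevel=2,
            )
            break
        _, current, chosen = best
        pool.remove(chosen)
        trajectory.append(current)
        report = evaluate_signature(current, target_seqs, other_seqs)
    return current, trajectory


def diagnose_gap_breaks(sig: Signature, seq: str) -> list[dict]:
    """Explain why a signature misses a sequence it should match.

    For each consecutive pattern pair whose literals both occur in the
    (ungapped) sequence, compares the observed spacing with the
    signature's fixed distance. Indels between patterns show up as a
    spacing mismatch; a missing literal (substitution or truncation)
    is reported as such. Returns one dict per broken link.
    """
    seq = seq.replace("-", "")
    problems: list[dict] = []
    positions: list[int | None] = []
    cursor = 0
    for pat in sig.patterns:
        hit = seq.find(pat.literal, cursor)
        positions.append(hit if hit >= 0 else None)
        if hit >= 0:
            cursor = hit + 1
    for i, (prev, cur) in enumerate(zip(sig.patterns, sig.patterns[1:])):
        p0, p1 = positions[i], positions[i + 1]
        expected = sig.gaps[i]
        if p0 is None or p1 is None:
            missing = prev.literal if p0 is None else cur.literal
            problems.append(
                {"gap_index": i, "expected": expected, "observed": None,
                 "reason": f"pattern {missing!r} not found"}
            )
            continue
        observed = p1 - (p0 + len(prev.literal))
        if observed != expected:
            problems.append(
                {"gap_index": i, "expected": expected, "observed": observed,
                 "reason": "inter-pattern distance mismatch"}
            )
    return problems


def select_candidate(evaluated: list[tuple[Signature, EvaluationReport]]) -> Signature:
    """Pick the candidate signature with the best F-measure.

    Ties break by higher recall, then fewer patterns, then shorter
    span, then lexicographically smaller regex — a total order, so the
    selection is deterministic.
    """
    if not evaluated:
        raise BarcodeError("no candidate signatures to select from")
    def key(item: tuple[Signature, EvaluationReport]):
        s, r = item
        return (-r.f_measure, -r.recall, len(s.patterns), s.span[2], s.regex)
    return min(evaluated, key=key)[0]
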