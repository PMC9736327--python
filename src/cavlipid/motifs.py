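"""Cholesterol-recognition and caveolin-binding motif scanning.

Three consensus classes are supported:

* **CARC** — ``(K/R)-X(1-5)-(Y/F)-X(1-5)-(L/V)`` read N-terminus to
  C-terminus; the membrane-proximal cholesterol-recognition consensus.
* **CRAC** — ``(L/V)-X(1-5)-(Y/F)-X(1-5)-(K/R)``, the mirror orientation of
  CARC along the chain.
* **CBM** — the caveolin-binding motif ``Phi-x-x-x-x-Phi-x-x-Phi`` with
  ``Phi`` an aromatic residue, fixed length 9.

``X``/``x`` gap positions accept any residue (including the unknown code
``X``); anchor positions never accept ``X``.  Every distinct (start, end)
span admitting a valid anchor parse is reported — overlapping and nested
spans included — because the biology of these motifs turns on their
overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from itertools import product

from .sequence import ProteinSequence

AROMATIC = frozenset("FWY")


class MotifClass(str, Enum):
    CRAC = "CRAC"
    CARC = "CARC"
    CBM = "CBM"


@dataclass(frozen=True)
class MotifElement:
    """One anchor position followed by a gap of variable length."""

    allowed: frozenset[str]
    gap_min: int = 0
    gap_max: int = 0


@dataclass(frozen=True)
class MotifPattern:
    """A gap-consensus pattern: anchors interleaved with bounded gaps."""

    motif_class: MotifClass
    elements: tuple[MotifElement, ...]

    @property
    def min_length(self) -> int:
        return len(self.elements) + sum(e.gap_min for e in self.elements[:-1])

    @property
    def max_length(self) -> int:
        return len(self.elements) + sum(e.gap_max for e in self.elements[:-1])


def carc_pattern(wide_center: bool = False) -> MotifPattern:
    """CARC consensus (K/R)-X1-5-(Y/F)-X1-5-(L/V).

    ``wide_center=True`` additionally allows W at the central aromatic
    position, a variant found in parts of the literature; the default keeps
    the strict Y/F form.
    """
    center = frozenset("YFW") if wide_center else frozenset("YF")
    return MotifPattern(
        MotifClass.CARC,
        (
            MotifElement(frozenset("KR"), 1, 5),
            MotifElement(center, 1, 5),
            MotifElement(frozenset("LV")),
        ),
    )


def crac_pattern(wide_center: bool = False) -> MotifPattern:
    """CRAC consensus (L/V)-X1-5-(Y/F)-X1-5-(K/R), the mirror of CARC."""
    center = frozenset("YFW") if wide_center else frozenset("YF")
    return MotifPattern(
        MotifClass.CRAC,
        (
            MotifElement(frozenset("LV"), 1, 5),
            MotifElement(center, 1, 5),
            MotifElement(frozenset("KR")),
        ),
    )


def cbm_pattern() -> MotifPattern:
    """Caveolin-binding motif Phi-xxxx-Phi-xx-Phi, Phi aromatic (F/W/Y)."""
    return MotifPattern(
        MotifClass.CBM,
        (
            MotifElement(AROMATIC, 4, 4),
            MotifElement(AROMATIC, 2, 2),
            MotifElement(AROMATIC),
        ),
    )


DEFAULT_PATTERNS = {
    MotifClass.CARC: carc_pattern,
    MotifClass.CRAC: crac_pattern,
    MotifClass.CBM: cbm_pattern,
}


@dataclass(frozen=True)
class MotifHit:
    """A located motif match.

    ``start``/``end`` are 1-based inclusive residue coordinates;
    ``anchors`` holds the coordinates of the defining residues of one
    representative parse (smallest first gap, then smallest second gap).
    """

    motif_class: MotifClass
    start: int
    end: int
    matched_subsequence: str
    anchors: tuple[int, ...]
    sequence_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def anchor_string(self, seq: ProteinSequence | None = None) -> str:
        """Human-readable anchors such as ``K81/Y85/L88``."""
        if seq is None:
            return "/".join(str(a) for a in self.anchors)
        return "/".join(f"{seq.slice(a, a)}{a}" for a in self.anchors)


def _parses(seq: str, pattern: MotifPattern, i: int) -> list[tuple[int, ...]]:
    """All anchor index tuples (0-based) for matches starting at index i."""
    out: list[tuple[int, ...]] = []
    elements = pattern.elements
    gap_ranges = [range(e.gap_min, e.gap_max + 1) for e in elements[:-1]]
    for gaps in product(*gap_ranges):
        pos = i
        idxs = []
        ok = True
        for k, elem in enumerate(elements):
            if pos >= len(seq) or seq[pos] not in elem.allowed:
                ok = False
                break
            idxs.append(pos)
            if k < len(elements) - 1:
                pos += 1 + gaps[k]
        if ok:
            out.append(tuple(idxs))
    return out


def scan(seq: ProteinSequence, pattern: MotifPattern) -> list[MotifHit]:
    """All distinct motif spans in ``seq`` matching ``pattern``.

    Each distinct (start, end) span with at least one valid anchor parse is
    reported exactly once, sorted by start then end, carrying the parse
    with the smallest first gap (ties broken by the second gap).
    """
    if len(seq) == 0:
        raise ValueError("cannot scan an empty sequence")
    residues = seq.residues
    spans: dict[tuple[int, int], tuple[int, ...]] = {}
    for i in range(len(residues)):
        for idxs in _parses(residues, pattern, i):
            key = (idxs[0], idxs[-1])
            # product() varies the first gap slowest, so the first parse
            # seen for a span has the smallest first gap (then second gap).
            if key not in spans:
                spans[key] = idxs
    hits = []
    for (s, e), idxs in sorted(spans.items()):
        start, end = seq.coordinate(s), seq.coordinate(e)
        hits.append(
            MotifHit(
                motif_class=pattern.motif_class,
                start=start,
                end=end,
                matched_subsequence=residues[s : e + 1],
                anchors=tuple(seq.coordinate(k) for k in idxs),
                sequence_id=seq.id,
            )
        )
    return hits


def scan_all(
    seq: ProteinSequence,
    classes: tuple[MotifClass, ...] = (MotifClass.CARC, MotifClass.CRAC, MotifClass.CBM),
    wide_center: bool = False,
) -> list[MotifHit]:
    """Scan one sequence for several motif classes; hits sorted by span."""
    hits: list[MotifHit] = []
    for cls in classes:
        factory = DEFAULT_PATTERNS[cls]
        pattern = factory(wide_center) if cls is not MotifClass.CBM else factory()
        hits.extend(scan(seq, pattern))
    return sorted(hits, key=lambda h: (h.start, h.end, h.motif_class.value))


@dataclass(frozen=True)
class OverlapRecord:
    """Intersection of two motif hits of different classes."""

    first: MotifHit
    second: MotifHit
    intersection_start: int
    intersection_end: int
    containment: bool  # one span entirely inside the other


def overlap_report(hits: list[MotifHit]) -> list[OverlapRecord]:
    """Pairwise overlaps between hits of *different* motif classes.

    All hits must come from the same sequence.  For each overlapping pair,
    the record carries the inclusive intersection interval and whether one
    span contains the other.
    """
    ids = {h.sequence_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits from multiple sequences: {sorted(ids)}")
    out = []
    for i, a in enumerate(hits):
        for b in hits[i + 1 :]:
            if a.motif_class == b.motif_class:
                continue
            lo = max(a.start, b.start)
            hi = min(a.end, b.end)
            if lo > hi:
                continue
            contained = (a.start <= b.start and b.end <= a.end) or (
                b.start <= a.start and a.end <= b.end
            )
            out.append(OverlapRecord(a, b, lo, hi, contained))
    return out
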