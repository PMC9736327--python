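"""Protein sequence container, FASTA input, and pairwise-alignment summaries.

Coordinates are 1-based and inclusive throughout, matching the residue
numbering conventions of protein biochemistry (e.g. the caveolin-2 CARC
domain K81...L88).  A :class:`ProteinSequence` may start at an arbitrary
residue number (``numbering_offset``) so that peptide fragments keep the
numbering of the parent protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Accepted in sequences but never matched by any motif anchor.
UNKNOWN_AA = "X"

VALID_AA = STANDARD_AA | {UNKNOWN_AA}

#: Strong similarity groups (conservative substitutions), the grouping used
#: by classic alignment pretty-printers.  Configurable in
#: :func:`identity_similarity`.
STRONG_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g)
    for g in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)

GAP_CHARS = set("-.")


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid sequence with 1-based residue numbering.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA header token before the first whitespace).
    residues : str
        Uppercase one-letter codes; the 20 standard residues plus ``X``.
    numbering_offset : int
        Residue number of the first character (default 1).  Character ``i``
        (0-based) of ``residues`` has residue coordinate
        ``numbering_offset + i``.
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if self.numbering_offset < 1:
            raise ValueError(
                f"numbering_offset must be >= 1, got {self.numbering_offset}"
            )
        object.__setattr__(self, "residues", self.residues.upper())
        for i, aa in enumerate(self.residues):
            if aa in GAP_CHARS:
                raise ValueError(
                    f"sequence {self.id!r} contains gap symbol {aa!r} at "
                    f"position {i + 1}; ungapped sequences are required"
                )
            if aa not in VALID_AA:
                raise ValueError(
                    f"sequence {self.id!r} contains invalid residue {aa!r} "
                    f"at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def start(self) -> int:
        """Residue coordinate of the first residue."""
        return self.numbering_offset

    @property
    def end(self) -> int:
        """Residue coordinate of the last residue."""
        return self.numbering_offset + len(self.residues) - 1

    def slice(self, start: int, end: int) -> str:
        """Residue string for the inclusive coordinate interval [start, end]."""
        if start < self.start or end > self.end or start > end:
            raise ValueError(
                f"[{start}, {end}] outside sequence range "
                f"[{self.start}, {self.end}]"
            )
        i = start - self.numbering_offset
        return self.residues[i : i + (end - start + 1)]

    def coordinate(self, index: int) -> int:
        """Residue coordinate for a 0-based string index."""
        return self.numbering_offset + index


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a multi-record FASTA file into :class:`ProteinSequence` objects.

    The header token before the first whitespace becomes the id; sequences
    are uppercased and numbered from 1.  Duplicate ids, empty files, gap
    symbols and non-amino-acid characters are rejected with messages naming
    the offending record and position.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for i, aa in enumerate(seq):
            if aa in GAP_CHARS:
                raise ValueError(
                    f"{path}: record {rec.id!r} contains gap symbol {aa!r} at "
                    f"position {i + 1}; supply ungapped sequences"
                )
            if aa not in VALID_AA:
                raise ValueError(
                    f"{path}: record {rec.id!r} contains non-amino-acid "
                    f"character {aa!r} at position {i + 1}"
                )
        out.append(ProteinSequence(id=rec.id, residues=seq))
    return out


def identity_similarity(
    aligned_a: str,
    aligned_b: str,
    similarity_groups: Sequence[Iterable[str]] = STRONG_GROUPS,
) -> tuple[float, float]:
    """Percent identity and similarity over a supplied pairwise alignment.

    Columns where both strings carry a gap are excluded from the
    denominator.  Identity counts columns with identical non-gap residues;
    similarity additionally counts residue pairs sharing at least one
    similarity group.  Both percentages are on the 0-100 scale.

    Raises
    ------
    ValueError
        If the strings differ in length or no scorable column exists.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError(
            f"aligned strings differ in length: {len(aligned_a)} vs {len(aligned_b)}"
        )
    groups = [frozenset(str(g).upper() for g in grp) for grp in similarity_groups]
    a = aligned_a.upper()
    b = aligned_b.upper()
    scored = identical = similar = 0
    for ca, cb in zip(a, b):
        gap_a, gap_b = ca in GAP_CHARS, cb in GAP_CHARS
        if gap_a and gap_b:
            continue
        scored += 1
        if gap_a or gap_b:
            continue
        if ca == cb:
            identical += 1
            similar += 1
        elif any(ca in g and cb in g for g in groups):
            similar += 1
    if scored == 0:
        raise ValueError("alignment has no scorable (non-double-gap) columns")
    return 100.0 * identical / scored, 100.0 * similar / scored
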