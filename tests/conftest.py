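import re

import numpy as np
import pytest

from cavlipid.sequence import ProteinSequence

#: Regex equivalents of the gap-consensus motifs, used only as the
#: independent brute-force oracle (re.fullmatch over every candidate span).
ORACLE_REGEX = {
    "CARC": r"[KR].{1,5}[YF].{1,5}[LV]",
    "CRAC": r"[LV].{1,5}[YF].{1,5}[KR]",
    "CBM": r"[FWY].{4}[FWY].{2}[FWY]",
}


def brute_force_spans(residues: str, motif_class: str, offset: int = 1):
    """All (start, end) spans matching the motif, by exhaustive enumeration."""
    pattern = re.compile(ORACLE_REGEX[motif_class])
    spans = []
    n = len(residues)
    for s in range(n):
        for e in range(s, n):
            if pattern.fullmatch(residues[s : e + 1]):
                spans.append((s + offset, e + offset))
    return spans


@pytest.fixture
def peptide_77_88() -> ProteinSequence:
    """The caveolin-2 fragment spanning residues 77-88 (offset 77)."""
    return ProteinSequence(id="cav2_frag", residues="FEISKYVMYKFL", numbering_offset=77)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231215)
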