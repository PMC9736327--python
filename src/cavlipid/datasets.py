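"""Bundled reference sequences.

Only small, public, canonical protein sequences are shipped: the human
caveolin-2 alpha isoform (UniProt P51636-1), the study protein, and the
human caveolin-1 alpha isoform (UniProt Q03135-1) for homology context.
"""

from __future__ import annotations

from .sequence import ProteinSequence

#: Human caveolin-2, alpha isoform (UniProt P51636-1), 162 residues.
#: Tryptophans sit at positions 70, 113 and 133; the CARC domain is
#: K81YVMYKFL88 and the caveolin-binding motif F77EISKYVMY85.
CAV2_ALPHA_HUMAN = (
    "MGLETEKADVQLFMDDDSYSHHSGLEYADPEKFADSDQDRDPHRLNSHLK"
    "LGFEDVIAEPVTTHSFDKVWICSHALFEISKYVMYKFLTVFLAIPLAFIA"
    "GILFATLSCLHIWILMPFVKTCLMVLPSVQTIWKSVTDVIIAPLCTSVGR"
    "SFSSVSLQLSQD"
)

#: Human caveolin-1, alpha isoform (UniProt Q03135-1), 178 residues.
CAV1_ALPHA_HUMAN = (
    "MSGGKYVDSEGHLYTVPIREQGNIYKPNNKAMADELSEKQVYDAHTKEID"
    "LVNRDPKHLNDDVVKIDFEDVIAEPEGTHSFDGIWKASFTTFTVTKYWFY"
    "RLLSALFGIPMALIWGIYFAILSFLHIWAVVPCIKSFLIEIQCISRVYSI"
    "YVHTVCDPLFEAVGKIFSNVRINLQKEI"
)


def cav2_alpha() -> ProteinSequence:
    """The study protein: human caveolin-2 alpha (UniProt P51636-1)."""
    return ProteinSequence(id="sp|P51636-1|CAV2_HUMAN", residues=CAV2_ALPHA_HUMAN)


def cav1_alpha() -> ProteinSequence:
    """Human caveolin-1 alpha (UniProt Q03135-1), for homology context."""
    return ProteinSequence(id="sp|Q03135-1|CAV1_HUMAN", residues=CAV1_ALPHA_HUMAN)
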