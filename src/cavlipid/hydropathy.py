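"""Interfacial hydropathy profiling and disorder-profile summaries.

The windowed hydropathy track is the classic membrane-protein diagnostic:
per-residue free energies of transfer from water to the POPC bilayer
interface (the Wimley-White interfacial scale, kcal/mol) are summed over a
sliding window (default 19 residues) and assigned to the window centre.
Windows with negative summed free energy partition favourably into the
membrane interface; maximal runs of favourable centres are reported as
candidate membrane-associated segments.

Disorder profiles (per-residue scores on a 0-1 scale from an external
predictor) are summarized, not predicted: the fraction of residues at or
above a threshold and the maximal above-threshold regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence import ProteinSequence

# Wimley & White (1996) interfacial scale: free energy of transfer
# (kcal/mol) of Ac-X-amide residues from water to the POPC bilayer
# interface.  Negative = favourable partitioning.  Charged forms for
# D/E/K/R and neutral histidine (the standard pH-7 choices).
WW_INTERFACIAL: dict[str, float] = {
    "A": 0.17, "R": 0.81, "N": 0.42, "D": 1.23, "C": -0.24,
    "Q": 0.58, "E": 2.02, "G": 0.01, "H": 0.17, "I": -0.31,
    "L": -0.56, "K": 0.99, "M": -0.23, "F": -1.13, "P": 0.45,
    "S": 0.13, "T": 0.14, "W": -1.85, "Y": -0.94, "V": 0.07,
}


@dataclass(frozen=True)
class HydropathyScale:
    """Named per-residue transfer free-energy scale (kcal/mol)."""

    name: str
    dg: dict[str, float]

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.dg)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")
        if not all(np.isfinite(v) for v in self.dg.values()):
            raise ValueError(f"scale {self.name!r} has non-finite values")

    @property
    def mean_value(self) -> float:
        return float(np.mean(list(self.dg.values())))


WW_INTERFACIAL_SCALE = HydropathyScale("ww-interfacial", WW_INTERFACIAL)

NAMED_SCALES = {"ww-interfacial": WW_INTERFACIAL_SCALE}


@dataclass(frozen=True)
class HydropathyProfile:
    """Windowed transfer free energies assigned to window centres.

    ``values[k]`` is the sum of per-residue free energies over the window
    centred at residue coordinate ``centers[k]``.  Terminal residues
    without a complete window carry no value.
    """

    sequence_id: str
    window_length: int
    centers: np.ndarray  # 1-based residue coordinates
    values: np.ndarray  # kcal/mol per window

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.values):
            raise ValueError("centers and values length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"center_residue": self.centers, "delta_g_kcal_mol": self.values}
        )


@dataclass(frozen=True)
class MembraneSegment:
    """Maximal run of membrane-favourable window centres.

    Coordinates are centre-residue coordinates by default; when expanded to
    full window coverage, ``expanded`` is True.
    """

    start: int
    end: int
    mean_dg: float
    min_dg: float
    expanded: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def compute_profile(
    seq: ProteinSequence,
    scale: HydropathyScale = WW_INTERFACIAL_SCALE,
    window_length: int = 19,
    impute_unknown: bool = False,
) -> HydropathyProfile:
    """Windowed hydropathy profile of ``seq`` under ``scale``.

    Parameters
    ----------
    window_length : int
        Odd window length; the value at centre ``c`` sums the scale over
        residues ``c - w//2 ... c + w//2``.  Default 19 (the span of a
        membrane-interface helix).
    impute_unknown : bool
        Replace ``X`` residues with the scale's mean value instead of
        raising.
    """
    if window_length < 1 or window_length % 2 == 0:
        raise ValueError(f"window_length must be odd and positive, got {window_length}")
    if len(seq) < window_length:
        raise ValueError(
            f"sequence {seq.id!r} (length {len(seq)}) shorter than window "
            f"{window_length}"
        )
    per_residue = np.empty(len(seq))
    for i, aa in enumerate(seq.residues):
        if aa in scale.dg:
            per_residue[i] = scale.dg[aa]
        elif aa == "X" and impute_unknown:
            per_residue[i] = scale.mean_value
        else:
            raise ValueError(
                f"residue {aa!r} at position {seq.coordinate(i)} has no value "
                f"in scale {scale.name!r} (enable impute_unknown to impute)"
            )
    values = np.convolve(per_residue, np.ones(window_length), mode="valid")
    half = window_length // 2
    centers = np.arange(half, len(seq) - half) + seq.numbering_offset
    return HydropathyProfile(
        sequence_id=seq.id,
        window_length=window_length,
        centers=centers,
        values=values,
    )


def call_segments(
    profile: HydropathyProfile,
    threshold: float = 0.0,
    min_centers: int = 1,
    expand: bool = False,
    sequence_range: tuple[int, int] | None = None,
) -> list[MembraneSegment]:
    """Maximal runs of window centres with ``value < threshold``.

    Runs shorter than ``min_centers`` are discarded.  By default segments
    are reported in centre-residue coordinates; with ``expand=True`` each
    run is widened by half a window on both sides (clipped to
    ``sequence_range`` when given) to cover every residue contributing to
    a favourable window.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    if min_centers < 1:
        raise ValueError("min_centers must be >= 1")
    fav = profile.values < threshold
    segments: list[MembraneSegment] = []
    half = profile.window_length // 2
    i = 0
    n = len(fav)
    while i < n:
        if not fav[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and fav[j + 1]:
            j += 1
        if j - i + 1 >= min_centers:
            start = int(profile.centers[i])
            end = int(profile.centers[j])
            vals = profile.values[i : j + 1]
            if expand:
                start -= half
                end += half
                if sequence_range is not None:
                    start = max(start, sequence_range[0])
                    end = min(end, sequence_range[1])
            segments.append(
                MembraneSegment(
                    start=start,
                    end=end,
                    mean_dg=float(np.mean(vals)),
                    min_dg=float(np.min(vals)),
                    expanded=expand,
                )
            )
        i = j + 1
    return segments


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder scores on the 0 (ordered) - 1 (disordered) scale."""

    scores: np.ndarray
    source: str = "unspecified"
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.size == 0:
            raise ValueError("empty disorder profile")
        if np.any(~np.isfinite(scores)) or np.any(scores < 0) or np.any(scores > 1):
            raise ValueError("disorder scores must be finite and within [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class DisorderSummary:
    fraction_disordered: float
    regions: tuple[tuple[int, int], ...]  # maximal runs >= threshold, 1-based
    threshold: float


def fraction_disordered(
    profile: DisorderProfile, threshold: float = 0.5
) -> DisorderSummary:
    """Fraction of residues with score >= threshold, plus maximal regions."""
    above = profile.scores >= threshold
    frac = float(np.mean(above))
    regions: list[tuple[int, int]] = []
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        regions.append(
            (i + profile.numbering_offset, j + profile.numbering_offset)
        )
        i = j + 1
    return DisorderSummary(frac, tuple(regions), threshold)


def read_disorder_tsv(path: str | Path, source: str = "file") -> DisorderProfile:
    """Read a two-column (residue_index, score) TSV disorder profile."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (residue_index, score)")
    idx = df.iloc[:, 0].to_numpy(dtype=int)
    if not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))):
        raise ValueError(f"{path}: residue indices must be consecutive")
    return DisorderProfile(
        scores=df.iloc[:, 1].to_numpy(dtype=float),
        source=source,
        numbering_offset=int(idx[0]),
    )
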