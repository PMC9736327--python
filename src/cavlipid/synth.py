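"""Seeded synthetic-data generators for every pipeline stage.

Each scenario produces both a data artifact (in the on-disk format the
corresponding stage reads) and a ground-truth record sufficient to score
that stage.  Identical (seed, scenario, overrides) triples produce
byte-identical output.

Scenario defaults encode the measured study conditions for the
caveolin-2 / lecithin-vesicle system and are collected in
:data:`SCENARIO_DEFAULTS` (bump :data:`DEFAULTS_VERSION` on any change):

======================  =====================================================
fret_titration          FRET-mediated DPH fluorescence increase vs protein,
                        Kd 0.75 uM, 8 points over 0-3 uM, noiseless default.
anisotropy_titration    DPH anisotropy vs protein at 30% cholesterol:
                        r(x) = 0.21 - 0.04 x/(0.48 + x); flat r = 0.12 at
                        0% / 5% cholesterol.
dph_quenching           donor (tryptophan) quenching vs DPH, hyperbola whose
                        fitted value at 2 uM equals 60%.
fret_saturation         saturating donor-only / donor+acceptor pair with
                        efficiency 0.16.
polarized_baseline      polarized intensity quadruple realizing a target
                        anisotropy (0.21 at 30% cholesterol) and G exactly.
dsc_three_condition     two-state thermograms ordered
                        Tm(buffer) < Tm(+SUV) < Tm(+SUV+chol).
motif_plant             random background sequence with motifs planted at
                        recorded spans.
cd_mixture              non-negative basis mixture plus Gaussian noise.
disorder_profile        beta-distributed scores with a set above-threshold
                        fraction.
======================  =====================================================

Where the study reports no number (fluorescence amplitudes in arbitrary
units, DSC Tm/dH values), defaults are round values marked
``artifact_choice`` in the table.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import cd as cdmod
from .dsc import Thermogram, two_state_cp, write_thermogram_tsv
from .fluorescence import (
    ObservableKind,
    PolarizedIntensities,
    TitrationSeries,
    polarized_from_anisotropy,
    write_titration_tsv,
)
from .hydropathy import DisorderProfile
from .sequence import ProteinSequence

DEFAULTS_VERSION = "1.0"

SCENARIOS = (
    "motif_plant",
    "cd_mixture",
    "fret_titration",
    "anisotropy_titration",
    "dph_quenching",
    "fret_saturation",
    "polarized_baseline",
    "dsc_three_condition",
    "disorder_profile",
)

#: Documented defaults per scenario.  Values without a measured anchor are
#: marked in the companion methods note as artifact choices.
SCENARIO_DEFAULTS: dict[str, dict[str, Any]] = {
    "fret_titration": {
        "kd_um": 0.75,  # half-maximal FRET-mediated fluorescence increase
        "baseline": 100.0,  # arbitrary fluorescence units (artifact choice)
        "p1": 50.0,  # amplitude, arbitrary units (artifact choice)
        "x_max_um": 3.0,
        "n_points": 8,
        "noise_sigma_fraction": 0.0,  # Gaussian sigma as a fraction of p1
    },
    "anisotropy_titration": {
        "condition": "30% cholesterol",
        "kd_um": 0.48,  # half-maximal anisotropy decrease
        "baseline_r": 0.21,  # DPH anisotropy, 30% cholesterol, no protein
        "amplitude_r": 0.04,  # plateau 0.17 at saturation
        "flat_r": 0.12,  # 0% / 5% cholesterol conditions
        "x_max_um": 3.0,
        "n_points": 8,
        "noise_sigma_fraction": 0.0,
    },
    "dph_quenching": {
        # fitted quenching at 2 uM DPH equals 60%:
        # p1 * 2 / (kd + 2) = 0.60 with p1 = 0.75 gives kd = 0.5
        "kd_um": 0.5,
        "max_quenching": 0.75,
        "f0": 100.0,  # donor fluorescence, arbitrary units (artifact choice)
        "x_max_um": 4.0,
        "n_points": 9,
        "noise_sigma_fraction": 0.0,
    },
    "fret_saturation": {
        "efficiency": 0.16,  # FRET efficiency at saturating protein
        "f_d": 100.0,  # donor-only signal (artifact choice)
    },
    "polarized_baseline": {
        "condition": "30% cholesterol",
        "target_r": 0.21,
        "g": 1.2,  # grating factor (artifact choice)
        "total_intensity": 300.0,  # corrected total (artifact choice)
        "i_90_90": 50.0,  # artifact choice; i_90_0 = g * i_90_90
    },
    "dsc_three_condition": {
        # no printed Tm/dH; ordering buffer < +SUV < +SUV+chol is the
        # measured trend, the numbers are artifact choices
        "tm_c": {"buffer": 55.0, "suv": 60.0, "suv_chol": 65.0},
        "dh_kj": {"buffer": 250.0, "suv": 300.0, "suv_chol": 350.0},
        "t_min_c": 20.0,
        "t_max_c": 95.0,
        "step_c": 0.25,
        "noise_sigma_fraction": 0.0,  # of peak height
    },
    "motif_plant": {
        "length": 120,
        "motifs": [
            {"motif_class": "CARC", "subsequence": "KYVMYKFL", "start": 81},
        ],
        "id": "synthetic_motif_plant",
    },
    "cd_mixture": {
        "fractions": {
            "regular_helix": 0.551,
            "distorted_helix": 0.211,
            "right_twist": 0.002,
            "turn": 0.077,
            "other": 0.158,
        },
        "noise_sigma_fraction": 0.0,  # of the mixture's max |ellipticity|
    },
    "disorder_profile": {
        "length": 162,
        "fraction_above": 0.46,
        "threshold": 0.5,
        "peak_region": (30, 50),  # residues biased toward the highest scores
    },
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded, reproducible generator configuration."""

    seed: int
    scenario: str
    overrides: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        allowed = set(SCENARIO_DEFAULTS[self.scenario])
        bad = set(self.overrides) - allowed
        if bad:
            raise ValueError(
                f"unknown override keys for {self.scenario!r}: {sorted(bad)} "
                f"(allowed: {sorted(allowed)})"
            )

    def params(self) -> dict[str, Any]:
        p = copy.deepcopy(SCENARIO_DEFAULTS[self.scenario])
        p.update(copy.deepcopy(self.overrides))
        return p


@dataclass(frozen=True)
class GeneratedArtifact:
    """A generated data object plus the ground truth that produced it."""

    scenario: str
    data: Any
    truth: dict[str, Any]


def _titration(
    rng: np.random.Generator,
    kind: ObservableKind,
    baseline: float,
    p1: float,
    kd: float,
    x_max: float,
    n_points: int,
    noise_sigma_fraction: float,
    condition: str = "",
) -> TitrationSeries:
    x = np.linspace(0.0, x_max, n_points)
    sign = 1.0 if kind.increasing else -1.0
    y = baseline + sign * p1 * x / (kd + x)
    if noise_sigma_fraction > 0:
        y = y + rng.normal(0.0, noise_sigma_fraction * p1, size=y.shape)
    return TitrationSeries(x=x, y=y, observable_kind=kind, condition=condition)


def generate(config: GeneratorConfig) -> GeneratedArtifact:
    """Generate the scenario's data artifact and ground-truth record."""
    rng = np.random.default_rng(config.seed)
    p = config.params()
    s = config.scenario

    if s == "fret_titration":
        series = _titration(
            rng,
            ObservableKind.FLUORESCENCE_INCREASE,
            p["baseline"],
            p["p1"],
            p["kd_um"],
            p["x_max_um"],
            p["n_points"],
            p["noise_sigma_fraction"],
            condition="LUV + DPH, FRET-mediated fluorescence",
        )
        truth = {
            "kd_um": p["kd_um"],
            "baseline": p["baseline"],
            "p1": p["p1"],
            "plateau": p["baseline"] + p["p1"],
        }
        return GeneratedArtifact(s, series, truth)

    if s == "anisotropy_titration":
        series = _titration(
            rng,
            ObservableKind.ANISOTROPY_DECREASE,
            p["baseline_r"],
            p["amplitude_r"],
            p["kd_um"],
            p["x_max_um"],
            p["n_points"],
            p["noise_sigma_fraction"],
            condition=p["condition"],
        )
        truth = {
            "kd_um": p["kd_um"],
            "baseline": p["baseline_r"],
            "p1": p["amplitude_r"],
            "plateau": p["baseline_r"] - p["amplitude_r"],
            "flat_r_low_cholesterol": p["flat_r"],
        }
        return GeneratedArtifact(s, series, truth)

    if s == "dph_quenching":
        x = np.linspace(0.0, p["x_max_um"], p["n_points"])
        q = p["max_quenching"] * x / (p["kd_um"] + x)
        y = p["f0"] * (1.0 - q)
        if p["noise_sigma_fraction"] > 0:
            noise = rng.normal(
                0.0, p["noise_sigma_fraction"] * p["f0"] * p["max_quenching"], x.shape
            )
            y = y + noise
            y[0] = p["f0"]  # reference point stays exact
        series = TitrationSeries(
            x=x,
            y=y,
            observable_kind=ObservableKind.DONOR_QUENCHING,
            condition="tryptophan donor vs DPH acceptor",
        )
        q_at_2 = p["max_quenching"] * 2.0 / (p["kd_um"] + 2.0)
        truth = {
            "kd_um": p["kd_um"],
            "max_quenching": p["max_quenching"],
            "f0": p["f0"],
            "percent_quenching_at_2um": 100.0 * q_at_2,
        }
        return GeneratedArtifact(s, series, truth)

    if s == "fret_saturation":
        f_d = p["f_d"]
        f_da = f_d * (1.0 - p["efficiency"])
        truth = {"efficiency": p["efficiency"], "f_d": f_d, "f_da": f_da}
        return GeneratedArtifact(s, {"f_d": f_d, "f_da": f_da}, truth)

    if s == "polarized_baseline":
        pol = polarized_from_anisotropy(
            p["target_r"], total=p["total_intensity"], g=p["g"]
        )
        quad = PolarizedIntensities(
            i_par=pol.i_par,
            i_perp=pol.i_perp,
            i_90_0=p["g"] * p["i_90_90"],
            i_90_90=p["i_90_90"],
        )
        truth = {"r": p["target_r"], "g": p["g"], "condition": p["condition"]}
        return GeneratedArtifact(s, quad, truth)

    if s == "dsc_three_condition":
        temp = np.arange(p["t_min_c"], p["t_max_c"] + p["step_c"] / 2, p["step_c"])
        data: dict[str, Thermogram] = {}
        for cond in ("buffer", "suv", "suv_chol"):
            tm, dh = p["tm_c"][cond], p["dh_kj"][cond]
            cp = two_state_cp(temp, tm, dh)
            if p["noise_sigma_fraction"] > 0:
                cp = cp + rng.normal(
                    0.0, p["noise_sigma_fraction"] * cp.max(), cp.shape
                )
            data[cond] = Thermogram(temp, cp, label=cond)
        truth = {"tm_c": dict(p["tm_c"]), "dh_kj": dict(p["dh_kj"])}
        return GeneratedArtifact(s, data, truth)

    if s == "motif_plant":
        # background drawn from residues that can never serve as motif
        # anchors, so planted spans are the only hits by construction
        background = "ADEGHINPQST"
        chars = list(rng.choice(list(background), size=p["length"]))
        planted = []
        for m in p["motifs"]:
            sub = m["subsequence"].upper()
            start = int(m["start"])
            i = start - 1
            if i < 0 or i + len(sub) > p["length"]:
                raise ValueError(f"planted motif {m} outside sequence of length {p['length']}")
            chars[i : i + len(sub)] = list(sub)
            planted.append(
                {
                    "motif_class": m["motif_class"],
                    "start": start,
                    "end": start + len(sub) - 1,
                    "subsequence": sub,
                }
            )
        seq = ProteinSequence(id=p["id"], residues="".join(chars))
        return GeneratedArtifact(s, seq, {"planted": planted})

    if s == "cd_mixture":
        basis = cdmod.default_basis()
        fr = dict(p["fractions"])
        total = sum(fr.values())
        fr = {k: v / total for k, v in fr.items()}
        spec = basis.mix(fr)
        el = spec.ellipticity
        if p["noise_sigma_fraction"] > 0:
            el = el + rng.normal(
                0.0, p["noise_sigma_fraction"] * np.abs(el).max(), el.shape
            )
        spec = cdmod.CDSpectrum(spec.wavelengths, el, label="synthetic mixture")
        return GeneratedArtifact(s, spec, {"fractions": fr})

    if s == "disorder_profile":
        n = p["length"]
        frac = p["fraction_above"]
        thr = p["threshold"]
        n_above = int(round(frac * n))
        scores = np.empty(n)
        # residues inside the peak region are preferentially disordered,
        # mimicking an N-terminal disordered stretch
        lo, hi = p["peak_region"]
        order = np.argsort(
            [abs(i + 1 - (lo + hi) / 2) for i in range(n)]
        )  # closest to the peak first
        above_idx = set(order[:n_above].tolist())
        for i in range(n):
            if i in above_idx:
                scores[i] = thr + (1.0 - thr) * rng.beta(2.0, 4.0)
            else:
                scores[i] = thr * rng.beta(2.0, 4.0)
        profile = DisorderProfile(scores=scores, source="synthetic")
        truth = {"fraction_above": n_above / n, "threshold": thr}
        return GeneratedArtifact(s, profile, truth)

    raise AssertionError(f"unhandled scenario {s!r}")  # pragma: no cover


def write_artifact(artifact: GeneratedArtifact, out_dir: str | Path) -> list[Path]:
    """Write the artifact in its stage's input format, plus truth.json.

    Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    s = artifact.scenario
    data = artifact.data

    if isinstance(data, TitrationSeries):
        path = out / f"{s}.tsv"
        write_titration_tsv(data, path)
        written.append(path)
    elif isinstance(data, ProteinSequence):
        path = out / f"{s}.fasta"
        with open(path, "w") as fh:
            fh.write(f">{data.id}\n")
            for i in range(0, len(data.residues), 60):
                fh.write(data.residues[i : i + 60] + "\n")
        written.append(path)
    elif isinstance(data, cdmod.CDSpectrum):
        path = out / f"{s}.tsv"
        cdmod.write_spectrum_tsv(data, path)
        written.append(path)
    elif isinstance(data, PolarizedIntensities):
        path = out / f"{s}.tsv"
        with open(path, "w") as fh:
            fh.write("x_uM\ti_par\ti_perp\ti_90_0\ti_90_90\n")
            fh.write(
                f"0.0\t{float(data.i_par)!r}\t{float(data.i_perp)!r}"
                f"\t{float(data.i_90_0)!r}\t{float(data.i_90_90)!r}\n"
            )
        written.append(path)
    elif isinstance(data, DisorderProfile):
        path = out / f"{s}.tsv"
        with open(path, "w") as fh:
            fh.write("residue_index\tscore\n")
            for i, sc in enumerate(data.scores):
                fh.write(f"{i + data.numbering_offset}\t{float(sc)!r}\n")
        written.append(path)
    elif isinstance(data, dict) and s == "dsc_three_condition":
        for cond, tg in data.items():
            path = out / f"{s}_{cond}.tsv"
            write_thermogram_tsv(tg, path)
            written.append(path)
    elif isinstance(data, dict) and s == "fret_saturation":
        path = out / f"{s}.json"
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        written.append(path)
    else:  # pragma: no cover
        raise TypeError(f"cannot serialize artifact for scenario {s!r}")

    truth_path = out / "truth.json"
    truth_path.write_text(
        json.dumps(artifact.truth, indent=2, sort_keys=True) + "\n"
    )
    written.append(truth_path)
    return written
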