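"""End-to-end analysis pipeline tying the stages together.

A :class:`RunConfig` names the input file for each enabled stage; ``run``
executes the enabled stages in dependency order, writes one
machine-readable report per stage plus a top-level summary, and logs every
parameter default actually used.  Reports are bit-stable: floats are
rounded to 4 significant digits in TSV output, full precision is kept in
JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import cd as cdmod
from . import dsc as dscmod
from . import fluorescence as fl
from . import hydropathy as hp
from . import motifs as mt
from .sequence import read_fasta
from .synth import DEFAULTS_VERSION

logger = logging.getLogger("cavlipid.pipeline")


def _sig4(x: float) -> str:
    return f"{x:.4g}"


@dataclass
class RunConfig:
    """Inputs and toggles for one pipeline run.

    A stage runs iff its input path is set and its toggle is True.
    """

    out_dir: str | Path = "cavlipid_out"
    seed: int = 0
    report_format: str = "json"  # json | tsv

    fasta: str | None = None
    run_motifs: bool = True
    run_hydropathy: bool = True
    window_length: int = 19
    dg_threshold: float = 0.0
    min_centers: int = 1

    disorder_profile: str | None = None
    disorder_threshold: float = 0.5

    cd_spectrum: str | None = None
    cd_basis: str | None = None

    titration: str | None = None
    fix_baseline: bool = False

    polarized: str | None = None

    thermogram: str | None = None
    dsc_pre_window: tuple[float, float] | None = None
    dsc_post_window: tuple[float, float] | None = None
    dsc_two_state: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("dsc_pre_window", "dsc_post_window"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(float(v) for v in raw[key])
        return cls(**raw)

    def enabled_stages(self) -> list[str]:
        stages = []
        if self.fasta and self.run_motifs:
            stages.append("motifs")
        if self.fasta and self.run_hydropathy:
            stages.append("hydropathy")
        if self.disorder_profile:
            stages.append("disorder")
        if self.cd_spectrum:
            stages.append("cd")
        if self.titration:
            stages.append("binding_fit")
        if self.polarized:
            stages.append("anisotropy")
        if self.thermogram:
            stages.append("dsc")
        return stages

    def validate(self) -> None:
        stages = self.enabled_stages()
        if not stages:
            raise ValueError("no stages enabled: supply at least one input")
        paths = {
            "motifs/hydropathy": self.fasta,
            "disorder": self.disorder_profile,
            "cd": self.cd_spectrum,
            "cd basis": self.cd_basis,
            "binding_fit": self.titration,
            "anisotropy": self.polarized,
            "dsc": self.thermogram,
        }
        for stage, p in paths.items():
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"stage {stage!r}: input not found: {p}")
        if self.thermogram and not (self.dsc_pre_window and self.dsc_post_window):
            raise ValueError(
                "stage 'dsc': dsc_pre_window and dsc_post_window are required"
            )


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the enabled stages and write reports under ``out_dir``.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("constants-table version %s", DEFAULTS_VERSION)
    summary: dict[str, Any] = {
        "defaults_version": DEFAULTS_VERSION,
        "seed": config.seed,
        "stages": {},
    }

    if "motifs" in config.enabled_stages():
        rows = []
        for seq in read_fasta(config.fasta):
            hits = mt.scan_all(seq)
            for h in hits:
                rows.append(
                    {
                        "sequence_id": h.sequence_id,
                        "motif_class": h.motif_class.value,
                        "start": h.start,
                        "end": h.end,
                        "subsequence": h.matched_subsequence,
                        "anchors": h.anchor_string(seq),
                    }
                )
        summary["stages"]["motifs"] = {"n_hits": len(rows), "hits": rows}
        _write_table(rows, out / "motifs", config.report_format)

    if "hydropathy" in config.enabled_stages():
        logger.info(
            "hydropathy: window=%d threshold=%g min_centers=%d (centre coordinates)",
            config.window_length,
            config.dg_threshold,
            config.min_centers,
        )
        seg_rows = []
        for seq in read_fasta(config.fasta):
            profile = hp.compute_profile(seq, window_length=config.window_length)
            profile.to_frame().to_csv(
                out / f"hydropathy_{_safe(seq.id)}.tsv", sep="\t", index=False
            )
            for seg in hp.call_segments(
                profile,
                threshold=config.dg_threshold,
                min_centers=config.min_centers,
            ):
                seg_rows.append(
                    {
                        "sequence_id": seq.id,
                        "start": seg.start,
                        "end": seg.end,
                        "mean_dg": float(_sig4(seg.mean_dg)),
                        "min_dg": float(_sig4(seg.min_dg)),
                        "coordinates": "window_center",
                    }
                )
        summary["stages"]["hydropathy"] = {
            "window_length": config.window_length,
            "segments": seg_rows,
        }
        _write_table(seg_rows, out / "segments", config.report_format)

    if "disorder" in config.enabled_stages():
        profile = hp.read_disorder_tsv(config.disorder_profile)
        ds = hp.fraction_disordered(profile, threshold=config.disorder_threshold)
        summary["stages"]["disorder"] = {
            "fraction_disordered": ds.fraction_disordered,
            "threshold": ds.threshold,
            "regions": [list(r) for r in ds.regions],
        }

    if "cd" in config.enabled_stages():
        spec = cdmod.read_spectrum_tsv(config.cd_spectrum)
        diag = cdmod.helix_ratio(spec)
        stage: dict[str, Any] = {
            "theta208": diag.theta208,
            "theta222": diag.theta222,
            "ratio_222_208": diag.ratio,
            "classification": diag.classification.value,
            "shape": diag.shape.value,
        }
        basis = (
            cdmod.read_basis_tsv(config.cd_basis)
            if config.cd_basis
            else cdmod.default_basis()
        )
        logger.info(
            "cd: basis=%s", config.cd_basis or "built-in synthetic reference basis"
        )
        dec = cdmod.deconvolve(spec, basis)
        stage["fractions"] = dec.fractions
        stage["residual_norm"] = dec.residual_norm
        summary["stages"]["cd"] = stage

    if "binding_fit" in config.enabled_stages():
        series = fl.read_titration_tsv(config.titration)
        fit = fl.fit_hyperbolic(
            series, fix_baseline=config.fix_baseline, seed=config.seed
        )
        summary["stages"]["binding_fit"] = _fit_record(fit)

    if "anisotropy" in config.enabled_stages():
        rows = []
        for x, pol in fl.read_polarized_tsv(config.polarized):
            rows.append(
                {"x_uM": x, "g": pol.grating_factor(), "r": fl.anisotropy(pol)}
            )
        summary["stages"]["anisotropy"] = {"points": rows}
        _write_table(rows, out / "anisotropy", config.report_format)

    if "dsc" in config.enabled_stages():
        tg = dscmod.read_thermogram_tsv(config.thermogram)
        corrected = dscmod.subtract_baseline(
            tg, config.dsc_pre_window, config.dsc_post_window
        )
        res = dscmod.analyze(corrected, two_state=config.dsc_two_state)
        summary["stages"]["dsc"] = {
            "tm_c": res.tm_c,
            "dh_cal_kj": res.dh_cal_kj,
            "dh_vh_kj": res.dh_vh_kj,
            "tm_fit_c": res.tm_fit_c,
        }

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary


def _fit_record(fit: fl.BindingFit) -> dict[str, Any]:
    return {
        "observable_kind": fit.observable_kind.value,
        "p1": fit.p1,
        "p1_stderr": fit.p1_stderr,
        "kd_um": fit.kd,
        "kd_stderr": fit.kd_stderr,
        "baseline": fit.baseline,
        "baseline_stderr": fit.baseline_stderr,
        "plateau": fit.plateau,
        "r_squared": fit.r_squared,
        "n_points": fit.n_points,
        "amplitude_zero": fit.amplitude_zero,
    }


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)


def _write_table(rows: list[dict], stem: Path, fmt: str) -> None:
    if fmt == "json":
        Path(f"{stem}.json").write_text(
            json.dumps(rows, indent=2, sort_keys=True) + "\n"
        )
        return
    if not rows:
        Path(f"{stem}.tsv").write_text("")
        return
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append(
            "\t".join(
                _sig4(v) if isinstance(v, float) else str(v) for v in (row[c] for c in cols)
            )
        )
    Path(f"{stem}.tsv").write_text("\n".join(lines) + "\n")
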