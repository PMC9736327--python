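"""Differential scanning calorimetry: baseline handling and two-state analysis.

A buffer-subtracted thermogram (temperature in degrees C, excess molar heat
capacity in kJ mol^-1 K^-1) is corrected with a linear chemical baseline
through flanking pre- and post-transition windows, then characterized by

* ``tm`` — temperature of maximum corrected heat capacity (with parabolic
  apex refinement);
* ``dh_cal`` — calorimetric enthalpy, the trapezoidal integral of the
  corrected excess heat capacity over the scan;
* ``dh_vh`` — van 't Hoff enthalpy from an optional two-state fit of

      cp(T) = dH^2 K / (R T^2 (1 + K)^2),
      K(T)  = exp[(dH / R)(1/Tm - 1/T)],   T in kelvin,

  with the folded/unfolded heat-capacity difference fixed at zero.

For a genuinely two-state transition dh_vh ~ dh_cal (cooperative unit of
one); lipid-induced stabilization appears as increases in both Tm and dH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

R_KJ = 8.314462618e-3  # gas constant, kJ mol^-1 K^-1
T0_K = 273.15


@dataclass(frozen=True)
class Thermogram:
    """Excess heat capacity vs temperature for one scan."""

    temperature_c: np.ndarray
    cp: np.ndarray  # kJ mol^-1 K^-1 (molar excess heat capacity)
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature_c, dtype=float)
        cp = np.asarray(self.cp, dtype=float)
        object.__setattr__(self, "temperature_c", t)
        object.__setattr__(self, "cp", cp)
        if t.shape != cp.shape or t.ndim != 1:
            raise ValueError("temperature and cp must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(cp))):
            raise ValueError("non-finite thermogram values")

    def __len__(self) -> int:
        return len(self.temperature_c)


def two_state_cp(
    temperature_c: np.ndarray, tm_c: float, dh_kj: float
) -> np.ndarray:
    """Two-state excess heat capacity (kJ mol^-1 K^-1), delta-Cp = 0."""
    t_k = np.asarray(temperature_c, dtype=float) + T0_K
    tm_k = tm_c + T0_K
    ln_k = (dh_kj / R_KJ) * (1.0 / tm_k - 1.0 / t_k)
    k = np.exp(np.clip(ln_k, -500, 500))
    return dh_kj**2 * k / (R_KJ * t_k**2 * (1.0 + k) ** 2)


def subtract_baseline(
    t: Thermogram,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    slope_warn_factor: float = 5.0,
) -> Thermogram:
    """Subtract a linear baseline through the pre/post window means.

    The baseline passes through (window centre, window mean cp) of the two
    flanking windows.  Windows must lie inside the scan, be disjoint, and
    come in (pre, post) order.  A window whose internal cp slope is much
    steeper than the global baseline slope is flagged as probably
    overlapping the transition.
    """
    lo, hi = t.temperature_c[0], t.temperature_c[-1]
    for name, (a, b) in (("pre", pre_window), ("post", post_window)):
        if a >= b:
            raise ValueError(f"{name}_window bounds must satisfy start < end")
        if a < lo or b > hi:
            raise ValueError(
                f"{name}_window [{a}, {b}] outside scan range [{lo}, {hi}]"
            )
    if pre_window[1] >= post_window[0]:
        raise ValueError(
            "pre_window must lie entirely below post_window "
            f"(got {pre_window} and {post_window})"
        )

    centers = []
    means = []
    slopes = []
    for a, b in (pre_window, post_window):
        mask = (t.temperature_c >= a) & (t.temperature_c <= b)
        if mask.sum() < 2:
            raise ValueError(f"window [{a}, {b}] contains fewer than 2 points")
        tt = t.temperature_c[mask]
        cc = t.cp[mask]
        centers.append(float(np.mean(tt)))
        means.append(float(np.mean(cc)))
        slopes.append(float(np.polyfit(tt, cc, 1)[0]))
    global_slope = (means[1] - means[0]) / (centers[1] - centers[0])
    slope_scale = max(abs(global_slope), 1e-12)
    for name, s in zip(("pre", "post"), slopes):
        if abs(s) > slope_warn_factor * slope_scale and abs(s) > 1e-9:
            warnings.warn(
                f"{name}-transition window slope ({s:.3g}) is much steeper than "
                "the global baseline; the window may overlap the transition",
                stacklevel=2,
            )
    baseline = means[0] + global_slope * (t.temperature_c - centers[0])
    return Thermogram(t.temperature_c.copy(), t.cp - baseline, label=t.label)


@dataclass(frozen=True)
class UnfoldingResult:
    """Tm and enthalpies extracted from a baseline-corrected thermogram."""

    tm_c: float  # apex of the corrected cp curve
    dh_cal_kj: float  # trapezoidal integral
    dh_vh_kj: float | None = None  # van 't Hoff enthalpy (two-state fit)
    tm_fit_c: float | None = None  # Tm parameter of the two-state fit
    fit_residual: float | None = None


def analyze(
    t: Thermogram,
    two_state: bool = True,
    noise_window_fraction: float = 0.1,
) -> UnfoldingResult:
    """Tm, calorimetric enthalpy, and optional two-state fit.

    Expects a baseline-corrected single-transition thermogram.  The peak
    must rise above the noise floor estimated from the first and last
    ``noise_window_fraction`` of the scan.  The apex is refined by a
    parabola through the maximum and its neighbours; dh_cal is the
    trapezoidal integral of cp over the scan.
    """
    if len(t) < 50:
        raise ValueError(f"need >= 50 points across the transition, got {len(t)}")
    cp = t.cp
    temp = t.temperature_c
    n_edge = max(int(len(t) * noise_window_fraction), 3)
    edge = np.concatenate([cp[:n_edge], cp[-n_edge:]])
    noise_floor = float(np.mean(edge) + 5.0 * np.std(edge))
    i_max = int(np.argmax(cp))
    if cp[i_max] <= max(noise_floor, 0.0):
        raise ValueError(
            f"no detectable transition: peak {cp[i_max]:.3g} below noise floor "
            f"{noise_floor:.3g}"
        )

    # parabolic apex refinement
    if 0 < i_max < len(t) - 1:
        t3 = temp[i_max - 1 : i_max + 2]
        c3 = cp[i_max - 1 : i_max + 2]
        a, b, _ = np.polyfit(t3, c3, 2)
        tm = float(-b / (2 * a)) if a < 0 else float(temp[i_max])
    else:
        tm = float(temp[i_max])

    dh_cal = float(np.trapezoid(cp, temp))

    dh_vh = tm_fit = residual = None
    if two_state:
        params = Parameters()
        params.add("tm_c", value=tm, min=temp[0], max=temp[-1])
        params.add("dh_kj", value=max(dh_cal, 10.0), min=1.0)

        def resid(p: Parameters) -> np.ndarray:
            return two_state_cp(temp, p["tm_c"].value, p["dh_kj"].value) - cp

        res = minimize(resid, params, method="leastsq")
        if res.success:
            dh_vh = float(res.params["dh_kj"].value)
            tm_fit = float(res.params["tm_c"].value)
            residual = float(np.sqrt(res.chisqr / len(t)))
        else:
            warnings.warn("two-state fit did not converge", stacklevel=2)
    return UnfoldingResult(
        tm_c=tm,
        dh_cal_kj=dh_cal,
        dh_vh_kj=dh_vh,
        tm_fit_c=tm_fit,
        fit_residual=residual,
    )


def read_thermogram_tsv(path: str | Path, label: str | None = None) -> Thermogram:
    """Two-column (temperature_C, cp) TSV with optional '#' metadata lines."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (temperature_C, cp)")
    return Thermogram(
        temperature_c=df.iloc[:, 0].to_numpy(dtype=float),
        cp=df.iloc[:, 1].to_numpy(dtype=float),
        label=label or path.stem,
    )


def write_thermogram_tsv(t: Thermogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        if t.label:
            fh.write(f"# label: {t.label}\n")
        fh.write("temperature_C\tcp_kJ_mol_K\n")
        for ti, ci in zip(t.temperature_c, t.cp):
            fh.write(f"{float(ti)!r}\t{float(ci)!r}\n")


def molar_normalize(
    power_cp: np.ndarray,
    protein_concentration_m: float,
    cell_volume_l: float,
) -> np.ndarray:
    """Convert instrument heat capacity (kJ/K for the cell) to molar units.

    Divides by the moles of protein in the cell
    (concentration x volume); use when raw instrument data rather than
    already-molar cp are supplied.
    """
    if protein_concentration_m <= 0 or cell_volume_l <= 0:
        raise ValueError("concentration and cell volume must be positive")
    moles = protein_concentration_m * cell_volume_l
    return np.asarray(power_cp, dtype=float) / moles
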