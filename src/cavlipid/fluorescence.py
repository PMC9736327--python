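"""Steady-state fluorescence analytics: anisotropy, FRET, binding fits.

Anisotropy is computed from polarized intensity pairs with the grating
(G) factor correction,

    r = (I_par - G * I_perp) / (I_par + 2 * G * I_perp),  G = I_90/0 / I_90/90,

where I_par and I_perp are the intensities with excitation/emission
polarizers at 0/0 and 0/90 degrees.

Binding titrations (fluorescence increase on membrane association,
anisotropy decrease on bilayer fluidization, donor quenching by an
acceptor) are fitted to the single-site hyperbola

    y(x) = baseline +/- P1 * x / (Kd + x)

by bounded nonlinear least squares, yielding the amplitude P1, the
half-maximal (dissociation) constant Kd, standard errors and R^2.

FRET efficiency is taken from donor quenching, E = 1 - F_DA / F_D.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize


class ObservableKind(str, Enum):
    FLUORESCENCE_INCREASE = "fluorescence_increase"
    DONOR_QUENCHING = "donor_quenching"
    ANISOTROPY_DECREASE = "anisotropy_decrease"

    @property
    def increasing(self) -> bool:
        return self is ObservableKind.FLUORESCENCE_INCREASE


@dataclass(frozen=True)
class PolarizedIntensities:
    """One polarized measurement; supply either the 90-degree pair or g."""

    i_par: float
    i_perp: float
    i_90_0: float | None = None
    i_90_90: float | None = None
    g: float | None = None

    def __post_init__(self) -> None:
        if self.i_par < 0 or self.i_perp < 0:
            raise ValueError("polarized intensities must be non-negative")
        if self.g is None and (self.i_90_0 is None or self.i_90_90 is None):
            raise ValueError("supply g or the (i_90_0, i_90_90) pair")

    def grating_factor(self) -> float:
        if self.i_90_0 is not None and self.i_90_90 is not None:
            return g_factor(self.i_90_0, self.i_90_90)
        assert self.g is not None
        if self.g <= 0:
            raise ValueError(f"g must be positive, got {self.g}")
        return self.g


def g_factor(i_90_0: float, i_90_90: float) -> float:
    """Grating factor G = I_90/0 / I_90/90."""
    if i_90_0 <= 0 or i_90_90 <= 0:
        raise ValueError(
            f"grating intensities must be positive, got ({i_90_0}, {i_90_90})"
        )
    return i_90_0 / i_90_90


def anisotropy(p: PolarizedIntensities) -> float:
    """Steady-state anisotropy r = (I_par - G I_perp)/(I_par + 2 G I_perp)."""
    g = p.grating_factor()
    denom = p.i_par + 2.0 * g * p.i_perp
    if denom <= 0:
        raise ValueError("zero total intensity: anisotropy undefined")
    return (p.i_par - g * p.i_perp) / denom


def polarized_from_anisotropy(
    r: float, total: float = 300.0, g: float = 1.0
) -> PolarizedIntensities:
    """Polarized intensity pair realizing anisotropy ``r`` exactly.

    ``total`` is the G-corrected total intensity I_par + 2 G I_perp.  The
    inverse of :func:`anisotropy`; used by the synthetic generators.
    """
    if not -0.5 <= r <= 1.0:
        raise ValueError(f"anisotropy {r} outside the physical range [-0.5, 1]")
    if total <= 0 or g <= 0:
        raise ValueError("total intensity and g must be positive")
    i_par = total * (1.0 + 2.0 * r) / 3.0
    i_perp = total * (1.0 - r) / (3.0 * g)
    return PolarizedIntensities(i_par=i_par, i_perp=i_perp, g=g)


@dataclass(frozen=True)
class TitrationSeries:
    """A titration: observable y versus titrant concentration x (uM)."""

    x: np.ndarray
    y: np.ndarray
    observable_kind: ObservableKind
    condition: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if np.any(np.diff(x) <= 0):
            raise ValueError("titrant concentrations must be strictly increasing")
        if x[0] < 0:
            raise ValueError("titrant concentrations must be non-negative")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite observable values")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class BindingFit:
    """Result of a hyperbolic single-site binding fit."""

    p1: float
    kd: float | None
    baseline: float
    observable_kind: ObservableKind
    p1_stderr: float | None
    kd_stderr: float | None
    baseline_stderr: float | None
    r_squared: float
    n_points: int
    amplitude_zero: bool = False

    @property
    def plateau(self) -> float:
        """Asymptotic observable: baseline + P1 (increase) or - P1 (decrease)."""
        sign = 1.0 if self.observable_kind.increasing else -1.0
        return self.baseline + sign * self.p1

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        kd = self.kd if self.kd is not None else np.inf
        sign = 1.0 if self.observable_kind.increasing else -1.0
        return self.baseline + sign * self.p1 * np.asarray(x, dtype=float) / (
            kd + np.asarray(x, dtype=float)
        )


def _hyperbola(params: Parameters, x: np.ndarray, sign: float) -> np.ndarray:
    return params["baseline"] + sign * params["p1"] * x / (params["kd"] + x)


def fit_hyperbolic(
    series: TitrationSeries,
    fix_baseline: bool = False,
    n_restarts: int = 3,
    seed: int = 0,
) -> BindingFit:
    """Fit y(x) = baseline +/- P1 x / (Kd + x) by bounded least squares.

    The sign follows ``series.observable_kind`` (minus for decreasing
    observables).  Initialization is data-driven: baseline = y(0),
    P1 = |y_last - y_first|, Kd = x at half amplitude by interpolation.
    ``fix_baseline`` pins the baseline to the x = 0 observation.  On
    non-convergence, up to ``n_restarts`` seeded random restarts are tried.

    A series whose amplitude is indistinguishable from zero is returned
    with ``amplitude_zero=True`` and ``kd=None`` (no reliable half point).
    """
    if len(series) < 5:
        raise ValueError(f"need at least 5 points to fit, got {len(series)}")
    x = series.x
    y = series.y
    sign = 1.0 if series.observable_kind.increasing else -1.0
    y0 = y[0] if x[0] == 0 else float(np.interp(0.0, x, y))
    amp0 = abs(y[-1] - y[0])
    yscale = max(np.ptp(y), abs(y).max(), 1e-12)

    if amp0 < 1e-12 * max(abs(y).max(), 1.0):
        # flat series: no binding signal to fit
        return BindingFit(
            p1=0.0,
            kd=None,
            baseline=float(np.mean(y)),
            observable_kind=series.observable_kind,
            p1_stderr=None,
            kd_stderr=None,
            baseline_stderr=None,
            r_squared=0.0,
            n_points=len(series),
            amplitude_zero=True,
        )

    # half-amplitude abscissa as the Kd starting value
    frac = np.abs(y - y[0]) / amp0
    kd0 = float(np.interp(0.5, frac, x))
    kd0 = min(max(kd0, 1e-6), x[-1] if x[-1] > 0 else 1.0)

    def build_params(p1_init: float, kd_init: float) -> Parameters:
        params = Parameters()
        params.add("baseline", value=y0, vary=not fix_baseline)
        params.add("p1", value=max(p1_init, 1e-12), min=0.0)
        params.add("kd", value=kd_init, min=1e-12)
        return params

    def residual(params: Parameters) -> np.ndarray:
        return _hyperbola(params, x, sign) - y

    rng = np.random.default_rng(seed)
    attempts = [(amp0, kd0)]
    attempts += [
        (amp0 * rng.uniform(0.3, 3.0), kd0 * rng.uniform(0.2, 5.0))
        for _ in range(n_restarts)
    ]
    best = None
    for p1_init, kd_init in attempts:
        try:
            res = minimize(residual, build_params(p1_init, kd_init), method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
        if res.success and res.chisqr <= yscale**2 * 1e-20:
            break
    if best is None or not best.success:
        raise RuntimeError(
            "hyperbolic fit failed to converge "
            f"(kind={series.observable_kind.value}, n={len(series)})"
        )

    p = best.params
    ss_res = float(np.sum(residual(p) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    p1 = float(p["p1"].value)
    p1_err = p["p1"].stderr
    amplitude_zero = p1 < 1e-9 * yscale or (
        p1_err is not None and p1_err > 0 and p1 < p1_err
    )
    if amplitude_zero:
        warnings.warn(
            "fitted amplitude indistinguishable from zero; Kd unreliable",
            stacklevel=2,
        )
    return BindingFit(
        p1=p1,
        kd=None if amplitude_zero else float(p["kd"].value),
        baseline=float(p["baseline"].value),
        observable_kind=series.observable_kind,
        p1_stderr=float(p1_err) if p1_err is not None else None,
        kd_stderr=(
            float(p["kd"].stderr)
            if (not amplitude_zero and p["kd"].stderr is not None)
            else None
        ),
        baseline_stderr=(
            float(p["baseline"].stderr)
            if p["baseline"].stderr is not None
            else None
        ),
        r_squared=r_squared,
        n_points=len(series),
        amplitude_zero=amplitude_zero,
    )


def fret_efficiency(f_da: float, f_d: float) -> float:
    """FRET efficiency from donor quenching, E = 1 - F_DA / F_D.

    Donor enhancement (F_DA > F_D) is reported as efficiency 0 with a
    warning rather than an error, so noisy pipelines keep running.
    """
    if f_d <= 0:
        raise ValueError(f"donor-only signal must be positive, got {f_d}")
    if f_da < 0:
        raise ValueError(f"donor+acceptor signal must be non-negative, got {f_da}")
    if f_da > f_d:
        warnings.warn(
            f"donor enhancement (F_DA={f_da} > F_D={f_d}); efficiency set to 0",
            stacklevel=2,
        )
        return 0.0
    return 1.0 - f_da / f_d


@dataclass(frozen=True)
class QuenchingCurve:
    """Hyperbolic fit of fractional donor quenching vs acceptor concentration."""

    fit: BindingFit

    def evaluate(self, concentration: float) -> float:
        """Percent donor quenching predicted at ``concentration`` (uM)."""
        if concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.fit.kd is None:
            return 0.0
        q = self.fit.p1 * concentration / (self.fit.kd + concentration)
        return 100.0 * q


def quenching_curve(series: TitrationSeries, **fit_kwargs) -> QuenchingCurve:
    """Fit donor fluorescence vs acceptor concentration to a quenching hyperbola.

    The donor series F(x) is converted to fractional quenching
    q(x) = 1 - F(x)/F(0), which is fitted to P1 * x / (Kd + x) with the
    baseline fixed at zero (q(0) = 0 by construction).
    """
    if series.x[0] != 0:
        raise ValueError("quenching series must include the x = 0 point")
    f0 = series.y[0]
    if f0 <= 0:
        raise ValueError("donor fluorescence at x = 0 must be positive")
    q = 1.0 - series.y / f0
    qseries = TitrationSeries(
        x=series.x,
        y=q,
        observable_kind=ObservableKind.FLUORESCENCE_INCREASE,
        condition=series.condition,
    )
    fit = fit_hyperbolic(qseries, fix_baseline=True, **fit_kwargs)
    return QuenchingCurve(fit)


def read_titration_tsv(path: str | Path) -> TitrationSeries:
    """TSV titration (x_uM, y) with '# observable_kind:' / '# condition:' headers."""
    path = Path(path)
    kind = ObservableKind.FLUORESCENCE_INCREASE
    condition = ""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("#").partition(":")
            key, val = key.strip(), val.strip()
            if key == "observable_kind":
                kind = ObservableKind(val)
            elif key == "condition":
                condition = val
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return TitrationSeries(
        x=df.iloc[:, 0].to_numpy(dtype=float),
        y=df.iloc[:, 1].to_numpy(dtype=float),
        observable_kind=kind,
        condition=condition,
    )


def write_titration_tsv(series: TitrationSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# observable_kind: {series.observable_kind.value}\n")
        if series.condition:
            fh.write(f"# condition: {series.condition}\n")
        fh.write("x_uM\ty\n")
        for xi, yi in zip(series.x, series.y):
            fh.write(f"{float(xi)!r}\t{float(yi)!r}\n")


def read_polarized_tsv(path: str | Path) -> list[tuple[float, PolarizedIntensities]]:
    """TSV of polarized rows: x_uM, i_par, i_perp[, i_90_0, i_90_90]."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    out = []
    has_pair = df.shape[1] >= 5
    for _, row in df.iterrows():
        p = PolarizedIntensities(
            i_par=float(row.iloc[1]),
            i_perp=float(row.iloc[2]),
            i_90_0=float(row.iloc[3]) if has_pair else None,
            i_90_90=float(row.iloc[4]) if has_pair else None,
            g=None if has_pair else 1.0,
        )
        out.append((float(row.iloc[0]), p))
    return out
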