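"""Far-UV circular-dichroism analytics.

Covers the standard desk workflow for protein far-UV CD:

* conversion of machine ellipticity (millidegrees) to mean residue
  ellipticity (MRE, deg cm^2 dmol^-1);
* the theta222/theta208 minima ratio, the classic coiled-coil diagnostic
  (ratio > 1: well-defined coiled coils; ratio <= 1: isolated helices);
* spectral-shape classification: 'w'-shaped spectra (troughs near 208 and
  222 nm, alpha-helical) versus 'v'-shaped spectra (single trough near
  217-220 nm, beta-rich);
* deconvolution into secondary-structure fractions by non-negative least
  squares against a basis of reference spectra.

The shipped basis is synthetic (smooth Gaussian-band shapes with the
canonical trough positions per class) and is intended for recovery testing
and as a documented placeholder; real analyses should supply an
experimentally derived basis via :func:`read_basis_tsv`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

#: Secondary-structure classes reported by the deconvolution.
STRUCTURE_CLASSES = (
    "regular_helix",
    "distorted_helix",
    "right_twist",
    "turn",
    "other",
)


class CoiledCoilClass(str, Enum):
    COILED_COIL = "coiled_coil"
    ISOLATED_HELICES = "isolated_helices"
    OTHER = "other"


class SpectralShape(str, Enum):
    W_SHAPED = "w_shaped"
    V_SHAPED = "v_shaped"
    OTHER = "other"


@dataclass(frozen=True)
class CDSpectrum:
    """A far-UV CD spectrum on a strictly increasing wavelength grid.

    ``ellipticity`` is mean residue ellipticity (deg cm^2 dmol^-1) unless
    the spectrum was constructed from raw machine units and not converted.
    """

    wavelengths: np.ndarray  # nm
    ellipticity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        el = np.asarray(self.ellipticity, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "ellipticity", el)
        if wl.shape != el.shape or wl.ndim != 1:
            raise ValueError("wavelengths and ellipticity must be equal-length 1-D")
        if len(wl) < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(el))):
            raise ValueError("non-finite values in spectrum")

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated ellipticity at ``wavelength`` (nm)."""
        wl = self.wavelengths
        if wavelength < wl[0] or wavelength > wl[-1]:
            raise ValueError(
                f"{wavelength} nm outside grid [{wl[0]}, {wl[-1]}] nm"
            )
        return float(np.interp(wavelength, wl, self.ellipticity))

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi


def to_mean_residue_ellipticity(
    wavelengths: np.ndarray,
    raw_mdeg: np.ndarray,
    path_length_cm: float,
    concentration_m: float,
    n_residues: int,
    label: str = "",
) -> CDSpectrum:
    """Convert machine ellipticity (mdeg) to mean residue ellipticity.

    MRE = raw_mdeg / (10 * l_cm * c_M * N_res), in deg cm^2 dmol^-1.
    """
    if path_length_cm <= 0:
        raise ValueError(f"path length must be positive, got {path_length_cm}")
    if concentration_m <= 0:
        raise ValueError(f"concentration must be positive, got {concentration_m}")
    if n_residues <= 0:
        raise ValueError(f"residue count must be positive, got {n_residues}")
    raw = np.asarray(raw_mdeg, dtype=float)
    mre = raw / (10.0 * path_length_cm * concentration_m * n_residues)
    return CDSpectrum(np.asarray(wavelengths, dtype=float), mre, label=label)


@dataclass(frozen=True)
class RatioDiagnostic:
    """The theta222/theta208 coiled-coil diagnostic for one spectrum."""

    theta222: float
    theta208: float
    ratio: float | None
    classification: CoiledCoilClass
    shape: SpectralShape


def helix_ratio(spec: CDSpectrum) -> RatioDiagnostic:
    """theta222/theta208 ratio with coiled-coil classification.

    The two ellipticities are read off the grid by linear interpolation.
    The ratio is computed only when both are negative (genuine helix
    troughs); classification is ``coiled_coil`` iff ratio > 1 (strict).
    """
    if not spec.covers(208.0, 222.0):
        raise ValueError(
            f"spectrum grid [{spec.wavelengths[0]}, {spec.wavelengths[-1]}] nm "
            "does not cover 208-222 nm"
        )
    t208 = spec.value_at(208.0)
    t222 = spec.value_at(222.0)
    shape = (
        classify_shape(spec) if spec.covers(205.0, 235.0) else SpectralShape.OTHER
    )
    if t208 >= 0 or t222 >= 0:
        return RatioDiagnostic(t222, t208, None, CoiledCoilClass.OTHER, shape)
    ratio = t222 / t208
    cls = (
        CoiledCoilClass.COILED_COIL
        if ratio > 1.0
        else CoiledCoilClass.ISOLATED_HELICES
    )
    return RatioDiagnostic(t222, t208, ratio, cls, shape)


def _local_minima(values: np.ndarray) -> list[int]:
    """Indices of strict-or-plateau local minima of a 1-D array."""
    mins = []
    n = len(values)
    for i in range(1, n - 1):
        left = values[i - 1]
        right = values[i + 1]
        if values[i] < left and values[i] < right:
            mins.append(i)
        elif values[i] < left and values[i] == right:
            # plateau: walk to its end; count once at plateau start
            j = i
            while j + 1 < n and values[j + 1] == values[i]:
                j += 1
            if j + 1 < n and values[j + 1] > values[i]:
                mins.append(i)
    return mins


def classify_shape(spec: CDSpectrum, smooth_points: int = 3) -> SpectralShape:
    """'w' vs 'v' spectral-shape call from trough positions.

    After a light moving-average smoothing (default width 3 grid points),
    local minima are located; the spectrum is ``w_shaped`` when distinct
    minima fall in 206-212 nm and 218-226 nm, ``v_shaped`` when a single
    minimum falls in 215-222 nm, and ``other`` otherwise.
    """
    if not spec.covers(205.0, 235.0):
        raise ValueError("shape classification needs the 205-235 nm range")
    el = spec.ellipticity
    if smooth_points > 1:
        kernel = np.ones(smooth_points) / smooth_points
        el = np.convolve(el, kernel, mode="same")
    idx = _local_minima(el)
    # only troughs inside the diagnostic 205-235 nm band are considered,
    # which keeps edge artifacts of the smoothing out of the call
    wl_min = [
        float(spec.wavelengths[i])
        for i in idx
        if 205.0 <= spec.wavelengths[i] <= 235.0
    ]
    in_208 = [w for w in wl_min if 206.0 <= w <= 212.0]
    in_222 = [w for w in wl_min if 218.0 <= w <= 226.0]
    if in_208 and in_222 and min(in_222) > max(in_208):
        return SpectralShape.W_SHAPED
    if len(wl_min) == 1 and 215.0 <= wl_min[0] <= 222.0:
        return SpectralShape.V_SHAPED
    return SpectralShape.OTHER


@dataclass(frozen=True)
class BasisSet:
    """Named reference spectra on a common wavelength grid."""

    wavelengths: np.ndarray
    spectra: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if len(set(self.spectra)) != len(self.spectra):
            raise ValueError("duplicate basis names")
        cleaned = {}
        for name, arr in self.spectra.items():
            a = np.asarray(arr, dtype=float)
            if a.shape != wl.shape:
                raise ValueError(f"basis member {name!r} not on the common grid")
            cleaned[name] = a
        object.__setattr__(self, "spectra", cleaned)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.spectra)

    def matrix(self) -> np.ndarray:
        """Column-per-class basis matrix."""
        return np.column_stack([self.spectra[n] for n in self.names])

    def mix(self, fractions: dict[str, float]) -> CDSpectrum:
        """Linear combination of basis members as a spectrum."""
        el = np.zeros_like(self.wavelengths)
        for name, f in fractions.items():
            el = el + f * self.spectra[name]
        return CDSpectrum(self.wavelengths.copy(), el, label="mixture")


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def default_basis(
    wavelengths: np.ndarray | None = None,
) -> BasisSet:
    """Synthetic reference basis with canonical trough/band positions.

    Regular helix: troughs at 208 and 222 nm with a strong positive band
    below 200 nm; distorted helix: the same bands broadened and attenuated;
    right twist (beta): single trough near 217 nm; turn: weak positive band
    near 225 nm with a shallow trough near 205 nm; other (irregular): deep
    trough near 198 nm.  Magnitudes are in the mean-residue-ellipticity
    range typical of far-UV protein CD (1e3 deg cm^2 dmol^-1 units).
    """
    wl = (
        np.arange(190.0, 260.0 + 0.5, 1.0)
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    spectra = {
        "regular_helix": (
            70.0 * _gaussian(wl, 192, 5.5)
            - 32.0 * _gaussian(wl, 208, 6.0)
            - 30.0 * _gaussian(wl, 222, 7.0)
        ),
        "distorted_helix": (
            35.0 * _gaussian(wl, 194, 7.0)
            - 18.0 * _gaussian(wl, 206, 9.0)
            - 12.0 * _gaussian(wl, 224, 10.0)
        ),
        "right_twist": (
            28.0 * _gaussian(wl, 196, 5.0) - 14.0 * _gaussian(wl, 217, 8.0)
        ),
        "turn": (
            -8.0 * _gaussian(wl, 205, 7.0) + 5.0 * _gaussian(wl, 225, 9.0)
        ),
        "other": (
            -35.0 * _gaussian(wl, 198, 7.5) + 4.0 * _gaussian(wl, 218, 12.0)
        ),
    }
    return BasisSet(wl, {k: v * 1e3 for k, v in spectra.items()})


@dataclass(frozen=True)
class DeconvolutionResult:
    """NNLS decomposition of a spectrum into basis fractions."""

    fractions: dict[str, float]  # normalized, sum to 1
    coefficients: dict[str, float]  # raw non-negative NNLS coefficients
    residual_norm: float

    def fraction_array(self, names: tuple[str, ...]) -> np.ndarray:
        return np.array([self.fractions[n] for n in names])


def deconvolve(
    spec: CDSpectrum, basis: BasisSet, condition_limit: float = 1e8
) -> DeconvolutionResult:
    """Non-negative least-squares decomposition into basis fractions.

    The basis is linearly interpolated onto the spectrum grid over the
    overlapping wavelength range; coefficients are constrained >= 0 and
    normalized to sum to 1 (raw coefficients also returned).  A basis with
    effectively collinear columns is rejected.
    """
    lo = max(spec.wavelengths[0], basis.wavelengths[0])
    hi = min(spec.wavelengths[-1], basis.wavelengths[-1])
    if lo >= hi:
        raise ValueError("spectrum and basis grids do not overlap")
    mask = (spec.wavelengths >= lo) & (spec.wavelengths <= hi)
    wl = spec.wavelengths[mask]
    y = spec.ellipticity[mask]
    A = np.column_stack(
        [np.interp(wl, basis.wavelengths, basis.spectra[n]) for n in basis.names]
    )
    if np.linalg.cond(A) > condition_limit:
        raise ValueError(
            "basis columns are collinear on the fitted grid "
            f"(condition number > {condition_limit:g})"
        )
    coef, residual = nnls(A, y)
    coefficients = dict(zip(basis.names, coef.tolist()))
    total = coef.sum()
    if total <= 0:
        raise ValueError("all deconvolution coefficients are zero")
    fractions = dict(zip(basis.names, (coef / total).tolist()))
    return DeconvolutionResult(fractions, coefficients, float(residual))


def read_spectrum_tsv(path: str | Path, label: str | None = None) -> CDSpectrum:
    """Two-column (wavelength_nm, ellipticity) TSV/CSV spectrum."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (wavelength_nm, ellipticity)")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    el = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(wl)
    return CDSpectrum(wl[order], el[order], label=label or path.stem)


def write_spectrum_tsv(spec: CDSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths, "ellipticity": spec.ellipticity}
    ).to_csv(path, sep="\t", index=False)


def read_basis_tsv(path: str | Path) -> BasisSet:
    """Multi-column basis TSV: wavelength_nm then one column per class."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected wavelength plus basis columns")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    spectra = {
        str(c): df[c].to_numpy(dtype=float) for c in df.columns[1:]
    }
    return BasisSet(wl, spectra)


def write_basis_tsv(basis: BasisSet, path: str | Path) -> None:
    cols = {"wavelength_nm": basis.wavelengths}
    cols.update(basis.spectra)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
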