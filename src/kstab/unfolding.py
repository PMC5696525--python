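"""Equilibrium-unfolding analysis from intrinsic fluorescence spectra.

Tryptophan emission red-shifts as the fluorophores become solvent exposed, so
the intensity-weighted mean emission wavelength (spectral center of mass, CM)
tracks unfolding. With fully-folded (0 M denaturant) and fully-unfolded
(maximum denaturant) reference spectra the CM maps linearly onto an unfolded
fraction fu, which is fitted with the two-state linear-extrapolation model:

    dG(x) = dG_water - m * x,      fu(x) = K / (1 + K),  K = exp(-dG(x)/RT)

where x is the denaturant molarity, m the denaturant sensitivity
(kcal/mol/M) and Cm = dG_water / m the transition midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: Gas constant in kcal/mol/K.
R_KCAL = 1.987e-3
#: Default temperature (K) for the linear-extrapolation fit.
T_DEFAULT = 298.15


@dataclass
class Spectrum:
    """A wavelength–intensity table on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 3:
            raise ValueError("spectrum needs at least 3 points")
        if self.intensities.shape != self.wavelengths.shape:
            raise ValueError("wavelengths and intensities differ in length")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")


def read_spectrum(path: str | Path, label: str = "") -> Spectrum:
    """Read a 2-column (wavelength, intensity) delimited text file.

    Lines starting with ``#`` and a single non-numeric header line are
    tolerated.
    """
    data = np.genfromtxt(str(path), comments="#", skip_header=0)
    if data.ndim == 1 or np.isnan(data).any():
        data = np.genfromtxt(str(path), comments="#", skip_header=1)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    return Spectrum(data[:, 0], data[:, 1], label=label or str(path))


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as 2-column (wavelength, intensity) text."""
    np.savetxt(str(path), np.column_stack([s.wavelengths, s.intensities]),
               header="wavelength_nm intensity")


@dataclass
class DenaturationSeries:
    """Spectra indexed by denaturant molarity; must include 0 M and a maximal
    reference condition (6 M in a typical GdnHCl experiment)."""

    molarities: Sequence[float]
    spectra: Sequence[Spectrum]

    def __post_init__(self) -> None:
        mol = np.asarray(self.molarities, dtype=float)
        if mol.size != len(self.spectra):
            raise ValueError("one spectrum per molarity required")
        if mol.size < 2:
            raise ValueError("need at least the 0 M and maximal references")
        if np.any(mol < 0) or len(set(mol.tolist())) != mol.size:
            raise ValueError("molarities must be distinct and non-negative")
        if 0.0 not in mol:
            raise ValueError("series must include the 0 M reference")
        self.molarities = mol


def center_of_mass(s: Spectrum) -> float:
    """Intensity-weighted mean wavelength, sum(I*lambda)/sum(I), in nm.

    Computed on the raw grid as a discrete sum (no interpolation).
    """
    total = s.intensities.sum()
    if total <= 0:
        raise ValueError("spectrum has no positive total intensity")
    return float((s.intensities * s.wavelengths).sum() / total)


def unfolded_fraction(cm_x: float, cm_0: float, cm_max: float,
                      flag_beyond: float = 0.1) -> float:
    """fu = (CM_0 - CM_x) / (CM_0 - CM_max).

    0 at the folded reference and 1 at the unfolded reference. Noise can push
    values slightly outside [0, 1]; they are returned unclipped, with a
    warning once past ``flag_beyond``.
    """
    if cm_0 == cm_max:
        raise ValueError("no transition amplitude: CM_0 equals CM_max")
    fu = (cm_0 - cm_x) / (cm_0 - cm_max)
    if fu < -flag_beyond or fu > 1 + flag_beyond:
        import warnings

        warnings.warn(f"unfolded fraction {fu:.3f} far outside [0, 1]",
                      stacklevel=2)
    return float(fu)


def series_to_fu(series: DenaturationSeries) -> pd.DataFrame:
    """Per-condition CM and unfolded fraction, referenced to 0 M and max M."""
    mol = np.asarray(series.molarities, dtype=float)
    cms = np.array([center_of_mass(s) for s in series.spectra])
    cm_0 = cms[np.argmin(mol)]
    cm_max = cms[np.argmax(mol)]
    fu = [unfolded_fraction(c, cm_0, cm_max) for c in cms]
    df = pd.DataFrame({"molarity": mol, "cm_nm": cms, "fu": fu})
    return df.sort_values("molarity", ignore_index=True)


@dataclass
class TwoStateFit:
    """Linear-extrapolation two-state fit result."""

    delta_g_water: float  # kcal/mol
    m_value: float  # kcal/mol/M
    cm: float  # M, = delta_g_water / m_value
    temperature: float  # K
    fitted_fu: np.ndarray
    residual_norm: float
    covariance: np.ndarray

    @property
    def delta_g_stderr(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def m_stderr(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))


def two_state_curve(x, delta_g_water: float, m_value: float,
                    temperature: float = T_DEFAULT):
    """fu(x) of the linear-extrapolation two-state model."""
    dg = delta_g_water - m_value * np.asarray(x, dtype=float)
    k = np.exp(-dg / (R_KCAL * temperature))
    return k / (1.0 + k)


def two_state_fit(fu_table: pd.DataFrame,
                  temperature: float = T_DEFAULT) -> TwoStateFit:
    """Least-squares fit of fu(molarity) to the two-state model.

    Requires at least 5 points spanning the transition (observed fu span
    >= 0.5); raises otherwise, since Cm is unconstrained without it.
    """
    x = np.asarray(fu_table["molarity"], dtype=float)
    fu = np.asarray(fu_table["fu"], dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points across the transition")
    if fu.max() - fu.min() < 0.5:
        raise ValueError(
            "no transition in range (fu span < 0.5); widen the denaturant range"
        )
    # midpoint guess: molarity where fu crosses 0.5
    order = np.argsort(x)
    cm_guess = float(np.interp(0.5, fu[order], x[order], left=x.min(),
                               right=x.max()))
    m_guess = 2.0
    p0 = (m_guess * max(cm_guess, 0.5), m_guess)

    def model(xv, dg, m):
        return two_state_curve(xv, dg, m, temperature)

    popt, pcov = curve_fit(model, x, fu, p0=p0, maxfev=20000)
    dg, m = float(popt[0]), float(popt[1])
    if m <= 0:
        raise ValueError("fit collapsed to non-positive m-value")
    fitted = model(x, dg, m)
    return TwoStateFit(
        delta_g_water=dg,
        m_value=m,
        cm=dg / m,
        temperature=temperature,
        fitted_fu=fitted,
        residual_norm=float(np.linalg.norm(fu - fitted)),
        covariance=pcov,
    )


def emission_maximum(s: Spectrum) -> float:
    """Wavelength of maximal intensity; ties resolve to the lower wavelength."""
    return float(s.wavelengths[int(np.argmax(s.intensities))])


def shift_report(reference: Spectrum, test: Spectrum,
                 window: tuple | None = None,
                 threshold_nm: float = 1.0) -> tuple:
    """Signed shift of the emission maximum and a red/blue/none call.

    The maximum is located inside ``window`` (nm) if given; shifts within
    ``threshold_nm`` of zero are classified ``"none"``.
    """
    lo = max(reference.wavelengths[0], test.wavelengths[0])
    hi = min(reference.wavelengths[-1], test.wavelengths[-1])
    if lo >= hi:
        raise ValueError("spectra have disjoint wavelength ranges")
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
        if lo >= hi:
            raise ValueError("window does not overlap both spectra")

    def _windowed_max(s: Spectrum) -> float:
        mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
        w, inten = s.wavelengths[mask], s.intensities[mask]
        return float(w[int(np.argmax(inten))])

    shift = _windowed_max(test) - _windowed_max(reference)
    if abs(shift) < threshold_nm or shift == 0:
        label = "none"
    else:
        label = "red" if shift > 0 else "blue"
    return shift, label
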