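"""Competitive-ELISA quantification via a logit standard curve.

In a competitive assay free analyte competes with plate-bound antigen for the
antibody, so absorbance *decreases* with analyte concentration. With Amax the
zero-competitor maximum and A0 the no-serum background, the normalized signal

    p = (A - A0) / (Amax - A0)

is logit-transformed; logit p is linear in log10 C over the working range,
which gives a two-parameter calibration line invertible for unknown samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Clip bound keeping the logit finite at the assay rails.
CLIP_EPS = 1e-6
#: Standards with p outside this band sit on the flat part of the curve.
WORKING_P = (0.1, 0.9)


class LogitResult(NamedTuple):
    value: float
    clipped: bool


def logit_p(a: float, a0: float, amax: float,
            eps: float = CLIP_EPS) -> LogitResult:
    """ln(p/(1-p)) of the normalized absorbance p = (A-A0)/(Amax-A0).

    p is clipped into [eps, 1-eps]; the flag reports whether clipping fired.
    """
    if amax <= a0:
        raise ValueError("Amax must exceed A0")
    p = (a - a0) / (amax - a0)
    clipped = not (eps <= p <= 1 - eps)
    p = min(max(p, eps), 1 - eps)
    return LogitResult(math.log(p / (1 - p)), clipped)


@dataclass
class ElisaStandardCurve:
    """Logit-transformed calibration line mapping absorbance to concentration."""

    a0: float
    amax: float
    standards: pd.DataFrame  # concentration, absorbance, replicate_sd, p, logit, flagged
    slope: float
    intercept: float
    r_squared: float
    working_range: tuple  # (C_low, C_high) where p stays inside WORKING_P


def fit_standard_curve(standards: Sequence, a0: float,
                       amax: float,
                       working_p: tuple = WORKING_P) -> ElisaStandardCurve:
    """Ordinary least squares of logit p on log10 C.

    ``standards`` is a sequence of (concentration, absorbance) or
    (concentration, absorbance, replicate_sd) tuples; replicate means should
    be supplied (replicates averaged before transformation). Standards whose
    p falls outside ``working_p`` are flagged but retained.
    """
    rows = []
    for item in standards:
        conc, a = item[0], item[1]
        sd = item[2] if len(item) > 2 else 0.0
        if conc <= 0:
            raise ValueError("standard concentrations must be positive")
        lr = logit_p(a, a0, amax)
        p = (a - a0) / (amax - a0)
        rows.append(
            {
                "concentration": float(conc),
                "absorbance": float(a),
                "replicate_sd": float(sd),
                "p": float(p),
                "logit_p": lr.value,
                "flagged": bool(
                    lr.clipped or not working_p[0] <= p <= working_p[1]
                ),
            }
        )
    df = pd.DataFrame(rows)
    if df["concentration"].nunique() < 4:
        raise ValueError("need >= 4 standards at distinct concentrations")
    logc = np.log10(df["concentration"].to_numpy())
    y = df["logit_p"].to_numpy()
    slope, intercept = np.polyfit(logc, y, 1)
    yhat = slope * logc + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope >= 0:
        raise ValueError(
            "non-negative slope: absorbance must fall with competitor "
            "concentration in a competitive assay"
        )
    usable = df[~df["flagged"]]
    rng_src = usable if len(usable) >= 2 else df
    working = (
        float(rng_src["concentration"].min()),
        float(rng_src["concentration"].max()),
    )
    return ElisaStandardCurve(
        a0=a0, amax=amax, standards=df, slope=float(slope),
        intercept=float(intercept), r_squared=r2, working_range=working,
    )


def fit_plate(plate: pd.DataFrame,
              working_p: tuple = WORKING_P) -> ElisaStandardCurve:
    """Fit the calibration line from a tidy plate table.

    Expects columns (well, role, concentration_or_dilution, absorbance) with
    roles ``a0``, ``amax``, ``standard`` (and optionally ``sample``);
    replicate wells are averaged before transformation.
    """
    def _mean(role: str) -> float:
        sub = plate[plate["role"] == role]
        if sub.empty:
            raise ValueError(f"plate has no {role!r} wells")
        return float(sub["absorbance"].mean())

    a0, amax = _mean("a0"), _mean("amax")
    stds = plate[plate["role"] == "standard"]
    grouped = stds.groupby("concentration_or_dilution")["absorbance"]
    standards = [
        (conc, grp.mean(), grp.std(ddof=1) if len(grp) > 1 else 0.0)
        for conc, grp in grouped
    ]
    return fit_standard_curve(standards, a0, amax, working_p=working_p)


def predict_samples(curve: ElisaStandardCurve,
                    plate: pd.DataFrame) -> pd.DataFrame:
    """Invert the curve for every sample well, averaging replicates per well.

    The plate's ``concentration_or_dilution`` column carries the dilution
    factor for sample wells. Returns one row per well with the predicted
    (dilution-corrected) concentration and an extrapolation flag.
    """
    rows = []
    samples = plate[plate["role"] == "sample"]
    if samples.empty:
        raise ValueError("plate has no sample wells")
    for well, grp in samples.groupby("well", sort=False):
        dilution = float(grp["concentration_or_dilution"].iloc[0])
        pred = predict_concentration(curve, float(grp["absorbance"].mean()),
                                     dilution)
        rows.append(
            {"well": well, "concentration": pred.concentration,
             "extrapolated": pred.extrapolated}
        )
    return pd.DataFrame(rows)


class Prediction(NamedTuple):
    concentration: float
    extrapolated: bool


def predict_concentration(curve: ElisaStandardCurve, a: float,
                          dilution: float = 1.0) -> Prediction:
    """Invert the calibration line for one absorbance reading.

    Returns the sample concentration scaled by its dilution factor; the flag
    marks readings outside the standards' concentration span.
    """
    if curve.slope == 0:
        raise ValueError("degenerate curve: zero slope")
    logit = logit_p(a, curve.a0, curve.amax).value
    logc = (logit - curve.intercept) / curve.slope
    conc = 10.0 ** logc
    lo = curve.standards["concentration"].min()
    hi = curve.standards["concentration"].max()
    return Prediction(conc * dilution, not lo <= conc <= hi)


class FaecalSample(NamedTuple):
    """One faecal extract: concentration (mg/mL), extract volume (mL), and
    the sampled vs total faecal mass (g) used to scale up."""

    concentration: float
    extract_volume: float
    sampled_mass: float
    total_mass: float


@dataclass(frozen=True)
class RecoveryResult:
    administered_mass: float  # mg
    recovered_mass: float  # mg
    recovery_percent: float


def recovery_percent(samples: Sequence, administered: float) -> RecoveryResult:
    """Mass balance of orally administered protein recovered in faeces.

    recovered = sum_i C_i * V_i * (total_i / sampled_i); the sampled/total
    scaling terms are explicit because each faecal collection is only
    partially extracted.
    """
    if administered <= 0:
        raise ValueError("administered mass must be positive")
    recovered = 0.0
    for s in samples:
        s = FaecalSample(*s)
        if s.sampled_mass <= 0:
            raise ValueError("sampled faecal mass must be positive")
        recovered += s.concentration * s.extract_volume * (
            s.total_mass / s.sampled_mass
        )
    return RecoveryResult(
        administered_mass=float(administered),
        recovered_mass=float(recovered),
        recovery_percent=100.0 * recovered / administered,
    )
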