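"""Ground-truthed synthetic inputs for every analysis stage.

Each generator emulates one experimental data stream — denaturant-dependent
red-shifting emission spectra, globular-particle scattering, competitive
ELISA plates, protein sequences with prescribed cleavage-site counts — and
returns, next to the data, a *truth record* sufficient to compute the
expected downstream result without re-running the generator. All generators
are seed-deterministic.

Defaults mirror a GdnHCl equilibrium-unfolding study of a ~300 kDa globular
egg carotenoprotein: emission recorded on 315–436 nm, denaturant 0–6 M with
a midpoint near 2.75 M, a compact particle with Rg ≈ 42 A, and a faecal
recovery scenario with ~83% of the administered dose recovered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import digestion, elisa
from .sequence_io import SubunitRecord
from .unfolding import DenaturationSeries, Spectrum, two_state_curve
from .saxs import SAXSCurve

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# denaturation series


def gen_denaturation_series(
    cm_folded: float = 340.0,
    cm_unfolded: float = 360.0,
    delta_g: float = 5.5,
    m_value: float = 2.0,
    molarities: Sequence[float] | None = None,
    peak_width: float = 12.0,
    noise_sd: float = 0.0,
    fu_noise_sd: float = 0.0,
    wavelengths: np.ndarray | None = None,
    seed: int = 0,
) -> tuple:
    """Two-state denaturation series of Gaussian emission peaks.

    Per molarity x the unfolded fraction follows the linear-extrapolation
    model (defaults dG_water = 5.5 kcal/mol, m = 2.0 kcal/mol/M, i.e.
    Cm = 2.75 M: essentially fully folded below 1.5 M and fully unfolded
    above 4 M); the spectrum is a unit-amplitude Gaussian centered at
    ``cm_folded + fu * (cm_unfolded - cm_folded)`` with additive intensity
    noise ``noise_sd``. ``fu_noise_sd`` perturbs the fraction itself before
    the spectrum is built (measurement noise expressed on the fu scale).

    Returns ``(DenaturationSeries, truth)`` where truth records the
    parameters and the noise-free fu per condition.
    """
    if cm_unfolded <= cm_folded:
        raise ValueError("unfolding must red-shift: cm_unfolded > cm_folded")
    rng = np.random.default_rng(seed)
    if molarities is None:
        molarities = np.linspace(0.0, 6.0, 21)
    molarities = np.asarray(molarities, dtype=float)
    if wavelengths is None:
        wavelengths = np.arange(315.0, 437.0, 1.0)

    spectra = []
    fu_true, fu_used = [], []
    for x in molarities:
        fu = float(two_state_curve(x, delta_g, m_value))
        fu_true.append(fu)
        fu_n = fu + (rng.normal(0.0, fu_noise_sd) if fu_noise_sd > 0 else 0.0)
        fu_used.append(fu_n)
        center = cm_folded + fu_n * (cm_unfolded - cm_folded)
        inten = np.exp(-0.5 * ((wavelengths - center) / peak_width) ** 2)
        if noise_sd > 0:
            inten = np.clip(inten + rng.normal(0.0, noise_sd, inten.shape), 0, None)
        spectra.append(Spectrum(wavelengths, inten, label=f"{x:.2f} M"))

    truth = {
        "delta_g_water": delta_g,
        "m_value": m_value,
        "cm": delta_g / m_value,
        "cm_folded": cm_folded,
        "cm_unfolded": cm_unfolded,
        "fu_true": fu_true,
        "fu_with_noise": fu_used,
        "molarities": molarities.tolist(),
        "seed": seed,
    }
    return DenaturationSeries(molarities, spectra), truth


# ---------------------------------------------------------------------------
# SAXS curves


def _sphere_form_factor(qr: np.ndarray) -> np.ndarray:
    """Normalized sphere scattering amplitude 3(sin x - x cos x)/x^3."""
    x = np.asarray(qr, dtype=float)
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = 3.0 * (np.sin(x[nz]) - x[nz] * np.cos(x[nz])) / x[nz] ** 3
    return out


def sphere_intensity(q: np.ndarray, radius: float, i0: float = 1.0) -> np.ndarray:
    """Analytic sphere scattering I(q) = I0 * Phi(qR)^2."""
    return i0 * _sphere_form_factor(np.asarray(q) * radius) ** 2


def ellipsoid_intensity(q: np.ndarray, a: float, c: float, i0: float = 1.0,
                        n_quad: int = 64) -> np.ndarray:
    """Orientation-averaged ellipsoid of revolution (semi-axes a, a, c).

    Averaged over the axis angle by Gauss–Legendre quadrature on cos(theta);
    each orientation scatters as a sphere of effective radius
    ``sqrt(a^2 (1-u^2) + c^2 u^2)``.
    """
    q = np.asarray(q, dtype=float)
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    u = 0.5 * (nodes + 1.0)  # map [-1,1] -> [0,1]
    w = 0.5 * weights
    reff = np.sqrt(a ** 2 * (1 - u ** 2) + c ** 2 * u ** 2)
    amp2 = _sphere_form_factor(np.outer(q, reff)) ** 2
    return i0 * amp2 @ w


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Analytic sphere pair-distance distribution (unnormalized shape).

    p(r) ∝ r^2 (1 - 3x/4 + x^3/16) with x = r/R, supported on [0, 2R].
    """
    x = np.asarray(r, dtype=float) / radius
    p = r ** 2 * (1 - 0.75 * x + x ** 3 / 16.0)
    return np.where((x >= 0) & (x <= 2), p, 0.0)


def gen_saxs_curve(
    body: str = "sphere",
    dimensions: float | tuple = 54.0,
    i0: float = 100.0,
    q_grid: np.ndarray | None = None,
    noise_model: str = "none",
    noise_frac: float = 0.01,
    noise_slope: float = 0.04,
    seed: int = 0,
) -> tuple:
    """Closed-form scattering from a sphere or ellipsoid of revolution.

    The default sphere radius 54 A gives Rg = sqrt(3/5)*54 ≈ 41.8 A, the
    size class of a compact ~300 kDa oligomer. ``noise_model="gaussian-relative"``
    adds Gaussian noise with SD ``(noise_frac + noise_slope * q/qmax) *
    sqrt(I * I0)`` — Poisson-like counting statistics that degrade toward
    high angle and do not vanish at form-factor minima; sigma is stored on
    the curve. Truth records Rg, Dmax and the generating parameters.
    """
    if q_grid is None:
        q_grid = np.linspace(0.004, 0.30, 300)
    q_grid = np.asarray(q_grid, dtype=float)

    if body == "sphere":
        radius = float(dimensions)
        if radius <= 0:
            raise ValueError("radius must be positive")
        intensity = sphere_intensity(q_grid, radius, i0)
        rg = math.sqrt(3.0 / 5.0) * radius
        dmax = 2.0 * radius
        dims = {"radius": radius}
    elif body == "ellipsoid":
        a, c = (float(dimensions[0]), float(dimensions[1]))
        if a <= 0 or c <= 0:
            raise ValueError("semi-axes must be positive")
        intensity = ellipsoid_intensity(q_grid, a, c, i0)
        rg = math.sqrt((2 * a ** 2 + c ** 2) / 5.0)
        dmax = 2.0 * max(a, c)
        dims = {"a": a, "c": c}
    else:
        raise ValueError(f"unknown body {body!r}")

    sigma = None
    if noise_model == "gaussian-relative":
        rng = np.random.default_rng(seed)
        rel = noise_frac + noise_slope * q_grid / q_grid[-1]
        # 1e-6*i0^2 floor keeps sigma positive at exact form-factor zeros
        sigma = rel * np.sqrt(np.maximum(intensity, 0.0) * i0 + 1e-6 * i0 ** 2)
        intensity = intensity + rng.normal(0.0, 1.0, q_grid.shape) * sigma
    elif noise_model != "none":
        raise ValueError(f"unknown noise model {noise_model!r}")

    curve = SAXSCurve(q=q_grid, intensity=intensity, sigma=sigma,
                      label=f"synthetic {body}")
    truth = {
        "body": body,
        "dimensions": dims,
        "i0": i0,
        "rg": rg,
        "dmax": dmax,
        "noise_model": noise_model,
        "seed": seed,
    }
    return curve, truth


# ---------------------------------------------------------------------------
# ELISA plates and the faecal-recovery scenario


def gen_elisa_plate(
    slope: float = -1.5,
    intercept: float = 0.0,
    a0: float = 0.05,
    amax: float = 1.50,
    standard_concs: Sequence[float] | None = None,
    samples: Sequence | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple:
    """Competitive-ELISA plate: absorbances fall with competitor concentration.

    Absorbance is generated by inverting the logit calibration:
    ``A(C) = A0 + (Amax - A0) * expit(slope * log10 C + intercept)`` plus
    Gaussian absorbance noise, independently per replicate well (assays are
    run in triplicate by default). ``samples`` is a sequence of
    ``(true_concentration, dilution)`` pairs; each is read at its diluted
    concentration. Returns ``(plate, truth)``; the plate is a tidy table
    with columns (well, role, concentration_or_dilution, replicate,
    absorbance).
    """
    if slope >= 0:
        raise ValueError("competitive assay requires a negative slope")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    if standard_concs is None:
        standard_concs = np.logspace(-1.5, 1.5, 8)
    samples = list(samples or [])

    def noisy(a: float) -> float:
        return a + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)

    def absorbance(conc: float) -> float:
        z = slope * math.log10(conc) + intercept
        p = 1.0 / (1.0 + math.exp(-z))
        return noisy(a0 + (amax - a0) * p)

    rows = []
    for rep in range(1, n_replicates + 1):
        rows.append({"well": "A0", "role": "a0",
                     "concentration_or_dilution": np.nan, "replicate": rep,
                     "absorbance": noisy(a0)})
        rows.append({"well": "Amax", "role": "amax",
                     "concentration_or_dilution": np.nan, "replicate": rep,
                     "absorbance": noisy(amax)})
        for k, conc in enumerate(standard_concs):
            rows.append(
                {"well": f"S{k + 1}", "role": "standard",
                 "concentration_or_dilution": float(conc), "replicate": rep,
                 "absorbance": absorbance(float(conc))}
            )
        for k, (true_conc, dilution) in enumerate(samples):
            rows.append(
                {"well": f"X{k + 1}", "role": "sample",
                 "concentration_or_dilution": float(dilution),
                 "replicate": rep,
                 "absorbance": absorbance(true_conc / dilution)}
            )
    plate = pd.DataFrame(rows)
    truth = {
        "slope": slope,
        "intercept": intercept,
        "a0": a0,
        "amax": amax,
        "standard_concs": [float(c) for c in standard_concs],
        "sample_concs": [float(c) for c, _ in samples],
        "sample_dilutions": [float(d) for _, d in samples],
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return plate, truth


def gen_recovery_scenario(
    administered: float = 2.1,
    recovery_pct: float = 83.0,
    n_samples: int = 6,
    extract_volume: float = 0.5,
    sampled_mass: float = 0.12,
    noise_sd: float = 0.0,
    seed: int = 0,
    **plate_kwargs,
) -> tuple:
    """Faecal-recovery experiment with a configured ground-truth recovery.

    The recovered mass ``administered * recovery_pct / 100`` (defaults: 2.1 mg
    administered, 83% recovered) is split across ``n_samples`` collections
    with random weights; each collection of total mass ~0.2-0.6 g has
    ``sampled_mass`` g extracted into ``extract_volume`` mL, fixing the true
    extract concentration. An ELISA plate reading those extracts (plus
    standards) is generated with :func:`gen_elisa_plate`.

    Returns ``(plate, sample_meta, truth)`` where ``sample_meta`` is a
    DataFrame of (extract_volume, sampled_mass, total_mass, dilution) rows
    aligned with the plate's sample wells.
    """
    rng = np.random.default_rng(seed)
    recovered = administered * recovery_pct / 100.0
    weights = rng.dirichlet(np.full(n_samples, 5.0))
    total_masses = rng.uniform(0.2, 0.6, n_samples)
    concs = []
    for w, total in zip(weights, total_masses):
        mass_in_sampled = recovered * w * (sampled_mass / total)
        concs.append(mass_in_sampled / extract_volume)  # mg/mL in extract

    # center the standard curve on the expected extract concentration, as an
    # analyst would when dilutions are planned around the anticipated dose
    expected_mid = recovered / n_samples * (sampled_mass / 0.4) / extract_volume
    slope = plate_kwargs.setdefault("slope", -1.5)
    plate_kwargs.setdefault("intercept", -slope * math.log10(expected_mid))
    plate_kwargs.setdefault(
        "standard_concs", expected_mid * np.logspace(-1.5, 1.5, 8)
    )
    samples = [(c, 1.0) for c in concs]
    plate, plate_truth = gen_elisa_plate(
        samples=samples, noise_sd=noise_sd,
        seed=int(rng.integers(0, 2 ** 31 - 1)), **plate_kwargs,
    )
    meta = pd.DataFrame(
        {
            "well": [f"X{k + 1}" for k in range(n_samples)],
            "extract_volume": extract_volume,
            "sampled_mass": sampled_mass,
            "total_mass": total_masses,
            "dilution": 1.0,
        }
    )
    truth = {
        "administered": administered,
        "recovery_pct": recovery_pct,
        "recovered_mass": recovered,
        "true_concs": concs,
        "plate": plate_truth,
        "seed": seed,
    }
    return plate, meta, truth


# ---------------------------------------------------------------------------
# sequences with prescribed cleavage-site counts


def gen_sequences(
    n: int = 1,
    length_range: tuple = (180, 210),
    target_sites: Mapping[str, int] | None = None,
    dialect: str = "peptidecutter",
    seed: int = 0,
    max_attempts: int = 50000,
) -> tuple:
    """Random protein sequences hitting exact per-protease cut-site counts.

    Sequences are rejection-sampled and point-mutated until
    :func:`kstab.digestion.find_cut_sites` matches every target exactly
    (greedy random search over single-residue edits, up to ``max_attempts``
    per sequence). With all targets zero, the residue pool simply excludes
    the proteases' P1 residues. Truth records the per-protease counts.
    """
    rng = np.random.default_rng(seed)
    target_sites = dict(target_sites or {})
    rules = digestion.builtin_rules(dialect)
    for name in target_sites:
        if name not in rules:
            raise KeyError(f"unknown protease {name!r}")
    active = {name: rules[name] for name in target_sites}

    pool = _RESIDUES
    if target_sites and all(v == 0 for v in target_sites.values()):
        banned = set().union(*(r.p1_residues for r in active.values()))
        pool = "".join(ch for ch in _RESIDUES if ch not in banned)

    def counts(seq: str) -> dict:
        return {
            name: len(digestion.find_cut_sites(seq, rule))
            for name, rule in active.items()
        }

    def loss(c: Mapping[str, int]) -> int:
        return sum(abs(c[k] - target_sites[k]) for k in target_sites)

    records, truth_counts = [], []
    for idx in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(list(pool), size=length))
        cur = counts(seq)
        attempts = 0
        while loss(cur) > 0:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"could not reach targets {target_sites} for length "
                    f"{length} within {max_attempts} edits"
                )
            pos = int(rng.integers(0, length))
            new = str(rng.choice(list(pool)))
            cand = seq[:pos] + new + seq[pos + 1:]
            cand_counts = counts(cand)
            if loss(cand_counts) <= loss(cur):
                seq, cur = cand, cand_counts
            attempts += 1
        records.append(SubunitRecord(id=f"syn{idx + 1}", sequence=seq))
        truth_counts.append(cur)

    truth = {
        "dialect": dialect,
        "target_sites": target_sites,
        "counts": truth_counts,
        "seed": seed,
    }
    return records, truth
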