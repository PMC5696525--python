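"""Small-angle X-ray scattering shape analysis.

Implements the primary one-dimensional SAXS toolbox for a globular particle:

* Guinier analysis with automated low-q window selection
  (ln I linear in q^2, slope -Rg^2/3, enforced qmax*Rg limit),
* Kratky and dimensionless Kratky transforms (globularity diagnostics),
* a regularized indirect Fourier transform recovering the pair-distance
  distribution P(r) on [0, Dmax], with non-negativity and endpoint-zero
  constraints, plus a Dmax scan.

The forward model for the IFT is
``I(q) = 4 pi * sum_j P(r_j) * sin(q r_j)/(q r_j) * dr`` on a uniform r-grid;
the inverse problem is solved as weighted least squares with a
second-difference smoothness penalty and a non-negativity constraint (NNLS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

#: Floor used when substituting missing uncertainties by sqrt(I).
SIGMA_EPS = 1e-10


@dataclass
class SAXSCurve:
    """A 1-D scattering curve: q (1/Angstrom), intensity, per-point sigma.

    If sigma is omitted a sqrt-intensity proxy ``sqrt(max(I, eps))`` is used
    and flagged via ``sigma_is_proxy``.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    sigma_is_proxy: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.size < 20:
            raise ValueError("need at least 20 scattering points")
        if self.intensity.shape != self.q.shape:
            raise ValueError("q and intensity differ in length")
        if np.any(self.q <= 0) or not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be positive and strictly increasing")
        if self.sigma is None:
            self.sigma = np.sqrt(np.maximum(self.intensity, SIGMA_EPS))
            self.sigma_is_proxy = True
        else:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma and q differ in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")


def read_dat(path: str | Path, label: str = "") -> SAXSCurve:
    """Read a 2–3 column (q, I[, sigma]) text file.

    Comment lines (``#``) are tolerated; q is assumed in 1/Angstrom unless a
    comment contains ``nm^-1`` or ``1/nm`` (then divided by 10).
    """
    path = Path(path)
    unit_nm = False
    rows = []
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            low = stripped.lower()
            if "nm^-1" in low or "1/nm" in low:
                unit_nm = True
            continue
        parts = stripped.replace(",", " ").split()
        try:
            vals = [float(p) for p in parts[:3]]
        except ValueError:
            continue  # header line
        if len(vals) >= 2:
            rows.append(vals)
    if len(rows) < 20:
        raise ValueError(f"{path}: fewer than 20 usable rows")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    q = arr[:, 0] / 10.0 if unit_nm else arr[:, 0]
    if not np.all(np.diff(q) > 0):
        raise ValueError(f"{path}: q column is not strictly increasing")
    sigma = arr[:, 2] if ncol >= 3 else None
    if sigma is not None and unit_nm is False:
        pass
    return SAXSCurve(q=q, intensity=arr[:, 1], sigma=sigma,
                     label=label or path.name)


def write_dat(curve: SAXSCurve, path: str | Path) -> None:
    """Write a curve as 3-column (q, I, sigma) text, q in 1/Angstrom."""
    np.savetxt(str(path),
               np.column_stack([curve.q, curve.intensity, curve.sigma]),
               header="q_invA intensity sigma")


@dataclass
class GuinierResult:
    """Automated Guinier fit: Rg, I0 and the window used."""

    rg: float  # Angstrom
    i0: float
    q_window: tuple
    qmax_rg: float
    slope: float
    intercept: float
    slope_stderr: float
    intercept_stderr: float
    n_points: int


def guinier_fit(curve: SAXSCurve, qmax_rg_limit: float = 1.3,
                min_points: int = 5, max_iter: int = 50,
                curvature_tol: float = 0.003) -> GuinierResult:
    """Iterative Guinier analysis of the low-q region.

    Starting from the lowest q with positive intensity, ln I is regressed on
    q^2; the upper bound is first moved to enforce ``qmax * Rg <= limit``
    (refitting until Rg changes by < 1% between iterations), then shrunk
    further while a quadratic term in q^2 still shifts the Rg estimate by
    more than ``curvature_tol`` — true Guinier data has no such term, so the
    refinement is a no-op there, while form-factor curvature (e.g. a sphere
    measured out to qRg = 1.3) triggers a tighter window.
    """
    usable = curve.intensity > 0
    start = int(np.argmax(usable))
    if not usable[start]:
        raise ValueError("no positive intensities")
    q = curve.q[start:]
    i = curve.intensity[start:]
    pos = i > 0
    q, i = q[pos], i[pos]
    if q.size < min_points:
        raise ValueError("too few positive low-q points for a Guinier fit")

    n_hi = min(q.size, max(min_points, 10))
    rg_prev = None
    for _ in range(max_iter):
        x = q[:n_hi] ** 2
        y = np.log(i[:n_hi])
        coeffs, cov = np.polyfit(x, y, 1, cov=True)
        slope, intercept = float(coeffs[0]), float(coeffs[1])
        if slope >= 0:
            raise ValueError("no Guinier decay: non-negative slope")
        rg = float(np.sqrt(-3.0 * slope))
        n_new = int(np.searchsorted(q, qmax_rg_limit / rg, side="right"))
        n_new = max(min_points, min(n_new, q.size))
        if rg_prev is not None and abs(rg - rg_prev) / rg_prev < 0.01 \
                and n_new == n_hi:
            break
        rg_prev, n_hi = rg, n_new
    else:
        raise ValueError("Guinier window selection did not converge")

    # curvature-driven shrink: drop high-q points while a q^4 term matters
    while n_hi > min_points:
        x = q[:n_hi] ** 2
        y = np.log(i[:n_hi])
        coeffs, cov = np.polyfit(x, y, 1, cov=True)
        slope, intercept = float(coeffs[0]), float(coeffs[1])
        if slope >= 0:
            raise ValueError("no Guinier decay: non-negative slope")
        rg = float(np.sqrt(-3.0 * slope))
        quad = np.polyfit(x, y, 2)
        if quad[1] >= 0:
            break
        rg_quad = float(np.sqrt(-3.0 * quad[1]))
        if abs(rg - rg_quad) / rg_quad <= curvature_tol:
            break
        n_hi -= max(1, n_hi // 10)

    return GuinierResult(
        rg=rg,
        i0=float(np.exp(intercept)),
        q_window=(float(q[0]), float(q[n_hi - 1])),
        qmax_rg=float(q[n_hi - 1] * rg),
        slope=slope,
        intercept=intercept,
        slope_stderr=float(np.sqrt(cov[0, 0])),
        intercept_stderr=float(np.sqrt(cov[1, 1])),
        n_points=n_hi,
    )


def kratky(curve: SAXSCurve) -> pd.DataFrame:
    """Pointwise Kratky transform (q, q^2 * I); no smoothing."""
    return pd.DataFrame({"q": curve.q, "q2I": curve.q ** 2 * curve.intensity})


def dimensionless_kratky(curve: SAXSCurve, g: GuinierResult) -> pd.DataFrame:
    """Normalized Kratky transform (qRg, (qRg)^2 * I/I0).

    For an ideal compact (Guinier-like) particle the curve peaks at
    qRg = sqrt(3) with height 3/e.
    """
    qrg = curve.q * g.rg
    return pd.DataFrame({"qRg": qrg, "qRg2I_I0": qrg ** 2 * curve.intensity / g.i0})


@dataclass
class PrCurve:
    """Pair-distance distribution on [0, Dmax] from the regularized IFT."""

    r: np.ndarray  # Angstrom grid, endpoints 0 and dmax
    p: np.ndarray  # P(r), zero at both endpoints
    dmax: float
    rg_real: float  # from P(r) moments
    i0_real: float
    alpha: float
    chi2_reduced: float
    sigma_was_proxy: bool

    def peak_r(self) -> float:
        """Location of the major P(r) peak (grid resolution)."""
        return float(self.r[int(np.argmax(self.p))])


def _design_matrix(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    qr = np.outer(q, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc = np.where(qr == 0, 1.0, np.sin(qr) / qr)
    dr = r[1] - r[0]
    return 4.0 * np.pi * sinc * dr


def _second_difference(n: int) -> np.ndarray:
    d = np.zeros((n - 2, n))
    for k in range(n - 2):
        d[k, k:k + 3] = (1.0, -2.0, 1.0)
    return d


def pr_invert(curve: SAXSCurve, dmax: float, alpha: float | None = None,
              n_points: int = 101) -> PrCurve:
    """Indirect Fourier transform: recover P(r) on [0, dmax].

    Solves ``min ||(A p - I)/sigma||^2 + alpha * ||D2 p||^2`` subject to
    ``p >= 0`` and ``p(0) = p(dmax) = 0`` (endpoints are excluded from the
    unknowns). ``alpha=None`` selects the penalty weight by an L-curve-style
    heuristic. Real-space invariants come from the moments of P(r):
    ``Rg^2 = \\int r^2 P dr / (2 \\int P dr)``, ``I0 = 4 pi \\int P dr``.
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    r = np.linspace(0.0, dmax, n_points)
    a_full = _design_matrix(curve.q, r)
    interior = slice(1, n_points - 1)
    a = a_full[:, interior] / curve.sigma[:, None]
    b = curve.intensity / curve.sigma
    d2 = _second_difference(n_points)[:, interior]

    if alpha is None:
        alpha = _lcurve_alpha(a, b, d2)

    stacked = np.vstack([a, np.sqrt(alpha) * d2])
    rhs = np.concatenate([b, np.zeros(d2.shape[0])])
    try:
        p_int, _ = nnls(stacked, rhs, maxiter=10 * stacked.shape[1])
    except RuntimeError as exc:  # pragma: no cover - pathological systems
        raise ValueError(
            "IFT system did not converge; try a larger alpha"
        ) from exc
    if not np.any(p_int > 0):
        raise ValueError("singular IFT solution; try a larger alpha")

    p = np.zeros(n_points)
    p[interior] = p_int
    dr = r[1] - r[0]
    integral = p.sum() * dr
    rg_real = float(np.sqrt((r ** 2 * p).sum() * dr / (2.0 * integral)))
    i0_real = float(4.0 * np.pi * integral)
    resid = a @ p_int - b
    dof = max(curve.q.size - np.count_nonzero(p_int), 1)
    return PrCurve(
        r=r,
        p=p,
        dmax=float(dmax),
        rg_real=rg_real,
        i0_real=i0_real,
        alpha=float(alpha),
        chi2_reduced=float(resid @ resid / dof),
        sigma_was_proxy=curve.sigma_is_proxy,
    )


def _lcurve_alpha(a: np.ndarray, b: np.ndarray, d2: np.ndarray) -> float:
    """Pick the smoothing weight at the corner of the residual/penalty trade-off.

    The candidate grid is scaled to the problem via the ratio of the data and
    penalty operator norms; the corner is the candidate maximizing curvature
    of the log-log L-curve, computed over a coarse 7-point scan.
    """
    scale = (np.linalg.norm(a, ord="fro") / max(np.linalg.norm(d2, ord="fro"),
                                                1e-12)) ** 2
    alphas = scale * np.logspace(-6, 0, 7)
    log_res, log_pen = [], []
    for al in alphas:
        stacked = np.vstack([a, np.sqrt(al) * d2])
        rhs = np.concatenate([b, np.zeros(d2.shape[0])])
        p, _ = nnls(stacked, rhs, maxiter=10 * stacked.shape[1])
        res = np.linalg.norm(a @ p - b)
        pen = np.linalg.norm(d2 @ p)
        log_res.append(np.log10(max(res, 1e-12)))
        log_pen.append(np.log10(max(pen, 1e-12)))
    log_res, log_pen = np.array(log_res), np.array(log_pen)
    # discrete curvature; endpoints excluded
    best, best_k = alphas[len(alphas) // 2], -np.inf
    for k in range(1, len(alphas) - 1):
        v1 = np.array([log_res[k] - log_res[k - 1], log_pen[k] - log_pen[k - 1]])
        v2 = np.array([log_res[k + 1] - log_res[k], log_pen[k + 1] - log_pen[k]])
        cross = v1[0] * v2[1] - v1[1] * v2[0]
        if cross > best_k:
            best_k, best = cross, alphas[k]
    return float(best)


def dmax_scan(curve: SAXSCurve, dmax_grid: Sequence[float],
              alpha: float | None = None, n_points: int = 101,
              rel_tol: float = 0.10,
              rg_guinier: float | None = None) -> tuple:
    """Run the IFT across candidate Dmax values and select the best support.

    Selection rule: the *smallest* Dmax whose reduced chi^2 is consistent
    with the grid minimum — the smallest support consistent with the data,
    which penalizes truncation without rewarding needless spread. A
    candidate counts as consistent when both
    ``chi2 <= chi2_min + rel_tol * (1 + chi2_min)`` (absolute slack when the
    best fit is essentially exact, relative slack when chi2_min is O(1)) and
    ``chi2 <= 100 * chi2_min`` (a support whose misfit is orders of
    magnitude above the minimum is truncated, however small both numbers
    are). Returns ``(best_dmax, table)`` with per-candidate fit quality for
    inspection.
    """
    grid = list(dmax_grid)
    if not grid:
        raise ValueError("dmax grid is empty")
    rows = []
    for d in grid:
        if rg_guinier is not None and d < 2.0 * rg_guinier:
            warnings.warn(
                f"dmax candidate {d} below 2*Rg_guinier = {2 * rg_guinier:.1f}",
                stacklevel=2,
            )
        pr = pr_invert(curve, d, alpha=alpha, n_points=n_points)
        dr = pr.r[1] - pr.r[0]
        smooth = float(np.sum(np.diff(pr.p, 2) ** 2))
        rows.append(
            {
                "dmax": float(d),
                "chi2_reduced": pr.chi2_reduced,
                "rg_real": pr.rg_real,
                "peak_r": pr.peak_r(),
                "smoothness": smooth,
                "tail_mass_frac": float(
                    pr.p[pr.r > 0.9 * d].sum() * dr
                    / max(pr.p.sum() * dr, 1e-300)
                ),
            }
        )
    table = pd.DataFrame(rows)
    chi_min = table["chi2_reduced"].min()
    threshold = min(chi_min + rel_tol * (1.0 + chi_min),
                    100.0 * (chi_min + 1e-12))
    ok = table[table["chi2_reduced"] <= threshold]
    best = float(ok["dmax"].min())
    return best, table
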