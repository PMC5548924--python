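"""Equilibrium binding analysis: one-site total-binding isotherms,
Scatchard linearization, and a bipartite-avidity model.

The total-binding isotherm fitted to plate/SPR data is

    y(x) = B_max * x / (K_d + x) + m * x + b

(specific saturable term, linear nonspecific term, constant background),
with x the *total* analyte concentration — the fitted K_d is therefore an
apparent K_d, as free-ligand depletion is not corrected.

The Scatchard linearization plots bound/free against bound: one-site
data fall on a line of slope -1/K_d, while tethered multi-site binding
produces characteristic curvature, which is reported as a low linear R^2
instead of a (meaningless) single K_d.

For two sites on one tethered ligand, simultaneous engagement enhances
the overall affinity through the effective concentration c_eff of the
second site once the first is bound:

    K_A,app = K_A1 + K_A2 + c_eff * K_A1 * K_A2,   K_d,app = 1 / K_A,app.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

#: Avogadro constant, 1/mol
_N_AVOGADRO = 6.02214076e23

SCATCHARD_R2_THRESHOLD = 0.9


@dataclass
class BindingCurve:
    """Dose-response points (total analyte concentration in uM)."""

    conc_uM: np.ndarray
    response: np.ndarray
    replicate: np.ndarray | None = None
    assay: str = "plate"

    def __post_init__(self) -> None:
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.replicate is None:
            self.replicate = np.zeros(len(self.conc_uM), dtype=int)
        if np.any(self.conc_uM < 0):
            raise ValueError("negative concentration")
        if len(np.unique(self.conc_uM)) < 4:
            raise ValueError("need >= 4 distinct concentrations for fitting")


@dataclass
class IsothermFit:
    kd_uM: float
    b_max: float
    ns_slope: float
    background: float
    rss: float
    apparent_kd: bool = True
    reliable: bool = True


@dataclass
class ScatchardResult:
    slope: float
    intercept: float
    kd_uM: float | None
    r_squared: float
    linear: bool
    n_points: int


def one_site_total(x: np.ndarray, kd: float, b_max: float, m: float, b: float) -> np.ndarray:
    return b_max * x / (kd + x) + m * x + b


def fit_one_site_total(curve: BindingCurve) -> IsothermFit:
    """Nonlinear least-squares fit of the one-site + background model.

    Multi-start over K_d initialized at the min, geometric mean and max
    of the (positive) concentration range, which avoids the shallow
    local minima of the total-binding surface; the best start by
    residual sum of squares wins.  A K_d pinned at the search bounds is
    flagged unreliable.
    """
    x = curve.conc_uM
    y = curve.response
    if np.allclose(y, y[0]):
        raise ValueError("degenerate curve: responses are all equal")
    xpos = x[x > 0]
    kd_starts = [float(xpos.min()), float(np.exp(np.mean(np.log(xpos)))), float(xpos.max())]
    span = float(y.max() - y.min())
    lo = [1e-6, 0.0, -np.inf, -np.inf]
    hi = [1e9, np.inf, np.inf, np.inf]

    def resid(p):
        return one_site_total(x, *p) - y

    best = None
    for kd0 in kd_starts:
        p0 = [kd0, span if span > 0 else 1.0, 0.0, float(y.min())]
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("isotherm fit failed from every start")
    rss, (kd, b_max, m, b) = best
    pinned = kd <= 2e-6 or kd >= 5e8
    return IsothermFit(float(kd), float(b_max), float(m), float(b), rss,
                       apparent_kd=True, reliable=not pinned)


def scatchard(
    curve: BindingCurve,
    r_max: float | None = None,
    r2_threshold: float = SCATCHARD_R2_THRESHOLD,
) -> ScatchardResult:
    """Scatchard analysis: weighted line through bound/free vs bound.

    Free ligand is approximated by the total analyte concentration
    (consistent with apparent-K_d reporting).  A K_d = -1/slope is
    reported only for a negative slope with linear R^2 at or above the
    threshold; curvature (multi-site behaviour) otherwise declines the
    estimate.
    """
    mask = (curve.conc_uM > 0) & (curve.response > 0)
    bound = curve.response[mask]
    free = curve.conc_uM[mask]
    if len(np.unique(free)) < 3:
        raise ValueError("need >= 3 usable concentrations")
    yv = bound / free
    xv = bound
    slope, intercept = np.polyfit(xv, yv, 1)
    pred = slope * xv + intercept
    ss_res = float(np.sum((yv - pred) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    linear = slope < 0 and r2 >= r2_threshold
    kd = float(-1.0 / slope) if linear else None
    return ScatchardResult(float(slope), float(intercept), kd, r2, linear, int(mask.sum()))


def avidity_apparent_kd(kd1_uM: float, kd2_uM: float, c_eff_uM: float) -> float:
    """Apparent K_d of a tethered two-site (avid) interaction in uM.

    ``1 / (1/K_d1 + 1/K_d2 + c_eff/(K_d1 K_d2))``; monotone decreasing
    in c_eff and never above min(K_d1, K_d2).
    """
    if kd1_uM <= 0 or kd2_uM <= 0:
        raise ValueError("site K_ds must be positive")
    if c_eff_uM < 0:
        raise ValueError("effective concentration must be non-negative")
    ka = 1.0 / kd1_uM + 1.0 / kd2_uM + c_eff_uM / (kd1_uM * kd2_uM)
    return 1.0 / ka


def c_eff_from_linker(
    n_residues: int,
    segment_length_A: float = 3.8,
) -> float:
    """Gaussian-chain effective concentration of a tethered site, in uM.

    Models the linker as an ideal chain of ``n`` segments of length
    ``b``; the probability density of zero end-to-end separation is
    ``W(0) = (3 / (2 pi n b^2))^(3/2)`` per cubic Angstrom, converted to
    molar units.  Idealizations: no excluded volume, no linker
    stiffness, sites treated as points — order-of-magnitude only.
    """
    if n_residues <= 0:
        raise ValueError("linker must contain at least one residue")
    msd = n_residues * segment_length_A**2  # <r^2> in A^2
    w0 = (3.0 / (2.0 * math.pi * msd)) ** 1.5  # A^-3
    molar = w0 * 1e27 / _N_AVOGADRO  # mol/L
    return molar * 1e6


def read_binding_table(path, assay: str = "plate") -> BindingCurve:
    """Read a TSV binding table with header ``conc_uM response replicate``."""
    df = pd.read_csv(path, sep=r"\s+")
    need = {"conc_uM", "response"}
    if not need.issubset(df.columns):
        raise ValueError(f"binding table needs columns {sorted(need)}")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return BindingCurve(df["conc_uM"].to_numpy(), df["response"].to_numpy(), rep, assay)
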