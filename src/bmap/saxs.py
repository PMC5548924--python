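"""Small-angle X-ray scattering: curve processing, Guinier/Kratky analysis,
coarse-grained Debye back-calculation and chi-square model fitting.

Back-calculation uses one bead per residue with a uniform form factor,

    I(q) = sum_ij f_i f_j sinc(q r_ij),

which is adequate for desk-scale shape discrimination between candidate
multidomain arrangements; it does not model the hydration shell or
atomic form factors, so absolute chi-square values are comparable only
within this convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .structures import StructureModel, StructureEnsemble

GUINIER_QRG_MAX = 1.3


@dataclass
class ScatteringCurve:
    """Three-column scattering data: q (1/Angstrom), I, sigma."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensities")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class GuinierFit:
    rg: float
    i0: float
    q_window: tuple[float, float]
    qrg_max: float
    n_points: int


@dataclass
class SaxsFitResult:
    chi2: float
    scale: float
    n_points: int
    label: str = ""


def read_curve(path, q_unit: str = "A^-1", label: str = "") -> ScatteringCurve:
    """Read whitespace three-column ``q I sigma`` text (ATSAS-style .dat).

    ``q_unit="nm^-1"`` converts to 1/Angstrom on read.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["q", "I", "sigma"])
    q = df["q"].to_numpy(float)
    if q_unit == "nm^-1":
        q = q / 10.0
    elif q_unit != "A^-1":
        raise ValueError(f"unknown q unit {q_unit!r}")
    return ScatteringCurve(q, df["I"].to_numpy(float), df["sigma"].to_numpy(float), label)


def write_curve(curve: ScatteringCurve, path) -> None:
    np.savetxt(path, np.column_stack([curve.q, curve.intensity, curve.sigma]),
               fmt="%.8g", header="q I sigma")


def scale_merge(curves: list[ScatteringCurve]) -> ScatteringCurve:
    """Scale curves to the first over the shared q-window, then average.

    Each later curve is multiplied by the least-squares factor matching
    it to the first on the overlapping grid; the scaled set is inverse-
    variance averaged point by point on the common grid.
    """
    if not curves:
        raise ValueError("no curves")
    if len(curves) == 1:
        return curves[0]
    ref = curves[0]
    lo = max(c.q[0] for c in curves)
    hi = min(c.q[-1] for c in curves)
    if lo >= hi:
        raise ValueError("curves have disjoint q-ranges")
    grid_mask = (ref.q >= lo) & (ref.q <= hi)
    grid = ref.q[grid_mask]
    scaled_I, scaled_var = [ref.intensity[grid_mask]], [ref.sigma[grid_mask] ** 2]
    for c in curves[1:]:
        I = np.interp(grid, c.q, c.intensity)
        s = np.interp(grid, c.q, c.sigma)
        # least-squares scale of this curve onto the reference
        k = float(np.sum(I * scaled_I[0]) / np.sum(I * I))
        scaled_I.append(k * I)
        scaled_var.append((k * s) ** 2)
    w = 1.0 / np.asarray(scaled_var)
    I_avg = np.sum(w * np.asarray(scaled_I), axis=0) / np.sum(w, axis=0)
    sigma_avg = np.sqrt(1.0 / np.sum(w, axis=0))
    return ScatteringCurve(grid, I_avg, sigma_avg, label="merged")


def guinier(curve: ScatteringCurve, qrg_max: float = GUINIER_QRG_MAX) -> GuinierFit:
    """Guinier analysis: weighted fit of ln I vs q^2 at low q.

    The window grows from the low-q end and is then trimmed iteratively
    so every fitted point satisfies q * Rg <= ``qrg_max``.  Fails
    explicitly for non-compact scatterers (non-negative slope).
    """
    pos = curve.intensity > 0
    q = curve.q[pos]
    I = curve.intensity[pos]
    sig = curve.sigma[pos]
    if len(q) < 5:
        raise ValueError("not enough positive-intensity points")
    n = len(q)
    for _ in range(200):
        x = q[:n] ** 2
        y = np.log(I[:n])
        w = (I[:n] / sig[:n]) ** 2  # sigma(ln I) = sigma/I
        slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
        if slope >= 0:
            raise ValueError("non-negative Guinier slope; scatterer not compact")
        rg = math.sqrt(-3.0 * slope)
        n_ok = int(np.searchsorted(q, qrg_max / rg, side="right"))
        if n_ok >= n or n_ok < 5:
            if n_ok < 5:
                n = 5
                x = q[:n] ** 2
                y = np.log(I[:n])
                slope, intercept = np.polyfit(x, y, 1, w=np.sqrt((I[:n] / sig[:n]) ** 2))
                if slope >= 0:
                    raise ValueError("non-negative Guinier slope in minimal window")
                rg = math.sqrt(-3.0 * slope)
            break
        n = n_ok
    return GuinierFit(rg, math.exp(intercept), (float(q[0]), float(q[n - 1])), qrg_max, n)


def kratky(curve: ScatteringCurve, compact_fraction: float = 0.5) -> tuple[pd.DataFrame, str]:
    """Kratky transform (q, q^2 I) and a compactness classification.

    "compact" when the transform falls below ``compact_fraction`` of its
    peak by the end of the measured range (peak-and-fall shape typical of
    folded particles); "flexible" when it plateaus or rises (Gaussian-
    chain-like q^-2 decay gives a constant transform).
    """
    t = curve.q**2 * curve.intensity
    df = pd.DataFrame({"q": curve.q, "q2I": t})
    peak = int(np.argmax(t))
    tail = float(t[-1])
    shape = "compact" if (peak < len(t) - 1 and tail < compact_fraction * t[peak]) else "flexible"
    return df, shape


def residue_beads(model: StructureModel) -> np.ndarray:
    """One bead per residue at the CA position (mean position fallback)."""
    beads = []
    for chain in np.unique(model.chains):
        cmask = model.chains == chain
        for res in np.unique(model.res_numbers[cmask]):
            rmask = cmask & (model.res_numbers == res)
            names = model.atom_names[rmask]
            if "CA" in names:
                beads.append(model.coords[rmask][names == "CA"][0])
            else:
                beads.append(model.coords[rmask].mean(axis=0))
    return np.asarray(beads)


def debye_curve(
    model: StructureModel,
    q: np.ndarray,
    form_factor: float = 1.0,
    drop_n_terminal: int = 0,
) -> ScatteringCurve:
    """Debye back-calculation on a one-bead-per-residue representation.

    ``drop_n_terminal`` removes that many residues from the N-terminus
    (lowest residue numbers) before the calculation — used to discard
    disordered tails that corrupt rigid-body fits.  The returned sigma
    column is a nominal 1% of I and carries no experimental meaning.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    beads = residue_beads(model)
    if drop_n_terminal:
        # beads are ordered by ascending residue number within each chain
        beads = beads[drop_n_terminal:] if drop_n_terminal < len(beads) else beads[:0]
    if len(beads) == 0:
        raise ValueError("empty bead model")
    f2 = form_factor * form_factor
    n = len(beads)
    if n == 1:
        I = np.full_like(q, f2)
    else:
        r = pdist(beads)
        I = np.empty_like(q)
        # chunk over q to bound the (n_q, n_pairs) workspace
        chunk = max(1, int(5e6 / max(len(r), 1)))
        for lo in range(0, len(q), chunk):
            qr = np.outer(q[lo:lo + chunk], r)
            I[lo:lo + chunk] = f2 * (n + 2.0 * np.sum(np.sinc(qr / np.pi), axis=1))
    sigma = np.maximum(0.01 * np.abs(I), 1e-12)
    return ScatteringCurve(q, I, sigma, label="debye")


def fit_curve(
    model: StructureModel | StructureEnsemble,
    experimental: ScatteringCurve,
    drop_n_terminal: int = 0,
    form_factor: float = 1.0,
) -> list[SaxsFitResult]:
    """Reduced chi-square of back-calculated model curves against data.

    chi^2 = (1/(N-1)) sum [(I_exp - c I_calc) / sigma]^2 with the scale
    c minimized in closed form.  Ensembles are fitted model by model.
    """
    if len(experimental) < 2:
        raise ValueError("need at least 2 experimental points")
    models = model.models if isinstance(model, StructureEnsemble) else [model]
    results = []
    for m in models:
        calc = debye_curve(m, experimental.q, form_factor=form_factor,
                           drop_n_terminal=drop_n_terminal)
        w = 1.0 / experimental.sigma**2
        num = float(np.sum(w * experimental.intensity * calc.intensity))
        den = float(np.sum(w * calc.intensity**2))
        c = num / den if den > 0 else 0.0
        chi2 = float(np.sum(w * (experimental.intensity - c * calc.intensity) ** 2)
                     / (len(experimental) - 1))
        results.append(SaxsFitResult(chi2, c, len(experimental), label=f"model{m.model_id}"))
    return results


def coordinate_rg(model: StructureModel) -> float:
    """Mass-uniform radius of gyration of the bead representation."""
    beads = residue_beads(model)
    center = beads.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((beads - center) ** 2, axis=1))))
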