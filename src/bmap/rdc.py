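"""Heteronuclear NOE flexibility analysis and RDC alignment-tensor fitting.

The {1H}-15N heteronuclear NOE ratio I_sat/I_ref reports fast backbone
motion; ratios below 0.5 flag flexible residues, with uncertainties from
Monte-Carlo resampling of the peak heights against the baseline noise.

Residual dipolar couplings constrain bond-vector orientation relative to
the molecular alignment frame.  For an N-H unit vector v the coupling is
the quadratic form D = v . S . v with S the (symmetric, traceless) Saupe
order matrix scaled to Hz; equivalently, in the principal frame

    D(theta, phi) = D_a * [(3 cos^2 theta - 1) + (3/2) R sin^2 theta cos 2 phi]

with axial component D_a = S_zz / 2 and rhombicity
R = 2 (S_xx - S_yy) / (3 S_zz), 0 <= R <= 2/3 under the ordering
|S_zz| >= |S_yy| >= |S_xx|.  Fitting the five independent Saupe elements
is a linear least-squares problem given >= 5 non-degenerate vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .structures import StructureModel

NOE_FLEXIBLE_CUTOFF = 0.5
N_MC_DEFAULT = 500

NH_BOND_LENGTH = 1.02  # Angstrom, amide N-H


# ---------------------------------------------------------------------------
# Heteronuclear NOE

def noe_ratio(
    table: pd.DataFrame,
    n_mc: int = N_MC_DEFAULT,
    seed: int | None = None,
) -> pd.DataFrame:
    """NOE ratios I_sat/I_ref with Monte-Carlo errors.

    ``table`` columns: residue, i_sat, i_ref, noise.  The error is the
    standard deviation of the ratio over ``n_mc`` draws with independent
    Gaussian noise added to both heights.  Residues whose reference
    intensity sits within 3 sigma of zero are flagged unusable.
    Columns out: residue, ratio, ratio_err, flexible, usable.
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in table.iterrows():
        i_sat, i_ref, sigma = float(r["i_sat"]), float(r["i_ref"]), float(r["noise"])
        if sigma <= 0:
            raise ValueError("noise sigma must be positive")
        if abs(i_ref) < 3 * sigma:
            rows.append((int(r["residue"]), math.nan, math.nan, False, False))
            continue
        ratio = i_sat / i_ref
        draws = (i_sat + rng.normal(0, sigma, n_mc)) / (i_ref + rng.normal(0, sigma, n_mc))
        err = float(np.std(draws, ddof=1))
        rows.append((int(r["residue"]), ratio, err, ratio < NOE_FLEXIBLE_CUTOFF, True))
    return pd.DataFrame(rows, columns=["residue", "ratio", "ratio_err", "flexible", "usable"])


def read_hetnoe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    need = {"residue", "i_sat", "i_ref", "noise"}
    if not need.issubset(df.columns):
        raise ValueError(f"hetNOE table needs columns {sorted(need)}")
    return df


# ---------------------------------------------------------------------------
# Alignment tensor

@dataclass
class AlignmentTensor:
    """Saupe order matrix in Hz with derived axial/rhombic components."""

    saupe: np.ndarray  # 3x3 symmetric traceless

    def __post_init__(self) -> None:
        S = np.asarray(self.saupe, dtype=float)
        if S.shape != (3, 3) or not np.allclose(S, S.T, atol=1e-9):
            raise ValueError("Saupe matrix must be 3x3 symmetric")
        if abs(np.trace(S)) > 1e-8 * max(1.0, np.abs(S).max()):
            raise ValueError("Saupe matrix must be traceless")
        self.saupe = 0.5 * (S + S.T)

    @classmethod
    def from_da_r(cls, d_a: float, rhombicity: float, rotation: np.ndarray | None = None) -> "AlignmentTensor":
        """Build a tensor from axial component (Hz) and rhombicity.

        The principal frame is the lab frame unless ``rotation`` (the
        matrix whose columns are the principal axes) is given.
        """
        if not 0 <= rhombicity <= 2.0 / 3.0 + 1e-12:
            raise ValueError("rhombicity must lie in [0, 2/3]")
        s_zz = 2.0 * d_a
        s_xx = -d_a + 1.5 * d_a * rhombicity
        s_yy = -d_a - 1.5 * d_a * rhombicity
        S = np.diag([s_xx, s_yy, s_zz])
        if rotation is not None:
            Q = np.asarray(rotation, float)
            S = Q @ S @ Q.T
        return cls(S)

    def principal(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues and axes ordered |S_zz| >= |S_yy| >= |S_xx|.

        Returned as (values[x, y, z], axes columns [x, y, z]).
        """
        vals, vecs = np.linalg.eigh(self.saupe)
        order = np.argsort(np.abs(vals))  # ascending |.| -> x, y, z
        return vals[order], vecs[:, order]

    @property
    def d_a(self) -> float:
        vals, _ = self.principal()
        return float(vals[2] / 2.0)

    @property
    def rhombicity(self) -> float:
        vals, _ = self.principal()
        if vals[2] == 0:
            return 0.0
        return float(2.0 * (vals[0] - vals[1]) / (3.0 * vals[2]))

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        """Couplings for an (N, 3) array of (not necessarily unit) vectors."""
        v = np.asarray(vectors, dtype=float)
        v = v / np.linalg.norm(v, axis=-1, keepdims=True)
        return np.einsum("ni,ij,nj->n", v, self.saupe, v)


@dataclass
class TensorFitResult:
    tensor: AlignmentTensor
    residues: np.ndarray
    d_obs: np.ndarray
    d_calc: np.ndarray
    q_factor: float
    rms: float

    @property
    def d_a(self) -> float:
        return self.tensor.d_a

    @property
    def rhombicity(self) -> float:
        return self.tensor.rhombicity


def _design_matrix(vectors: np.ndarray) -> np.ndarray:
    """Rows map the 5 Saupe unknowns (Sxx, Syy, Sxy, Sxz, Syz) to D."""
    v = vectors / np.linalg.norm(vectors, axis=-1, keepdims=True)
    x, y, z = v[:, 0], v[:, 1], v[:, 2]
    return np.column_stack([x**2 - z**2, y**2 - z**2, 2 * x * y, 2 * x * z, 2 * y * z])


def _saupe_from_params(p: np.ndarray) -> np.ndarray:
    sxx, syy, sxy, sxz, syz = p
    return np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, -sxx - syy]])


def nh_vectors(model: StructureModel, residues=None) -> tuple[np.ndarray, np.ndarray]:
    """Amide N->H unit vectors; H built geometrically when absent.

    A missing amide proton is placed 1.02 Angstrom from N along the
    in-plane direction opposite the bisector of N->CA and N->C(i-1);
    residues lacking the needed heavy atoms are skipped.
    Returns (residue numbers, (N, 3) unit vectors).
    """
    resnums = sorted(set(int(r) for r in model.res_numbers))
    if residues is not None:
        wanted = set(int(r) for r in residues)
        resnums = [r for r in resnums if r in wanted]
    out_res, out_vec = [], []
    for res in resnums:
        try:
            n_pos = model.atom_coord(res, "N")
        except KeyError:
            continue
        h_pos = None
        for hname in ("H", "HN"):
            try:
                h_pos = model.atom_coord(res, hname)
                break
            except KeyError:
                pass
        if h_pos is None:
            try:
                ca = model.atom_coord(res, "CA")
                c_prev = model.atom_coord(res - 1, "C")
            except KeyError:
                continue
            u1 = (ca - n_pos) / np.linalg.norm(ca - n_pos)
            u2 = (c_prev - n_pos) / np.linalg.norm(c_prev - n_pos)
            d = -(u1 + u2)
            nd = np.linalg.norm(d)
            if nd < 1e-8:
                continue
            h_pos = n_pos + NH_BOND_LENGTH * d / nd
        vec = h_pos - n_pos
        out_res.append(res)
        out_vec.append(vec / np.linalg.norm(vec))
    return np.array(out_res, dtype=int), np.asarray(out_vec, dtype=float).reshape(-1, 3)


def fit_tensor_svd(
    rdcs: pd.DataFrame,
    model: StructureModel,
) -> TensorFitResult:
    """Least-squares Saupe-matrix fit of observed N-H RDCs to a structure.

    ``rdcs`` columns: residue, d_obs_hz (error_hz/medium optional).
    Raises on fewer than 5 usable couplings or degenerate geometry.
    """
    res_all, vec_all = nh_vectors(model)
    lookup = {int(r): v for r, v in zip(res_all, vec_all)}
    residues, vectors, d_obs = [], [], []
    for _, row in rdcs.iterrows():
        r = int(row["residue"])
        if r in lookup:
            residues.append(r)
            vectors.append(lookup[r])
            d_obs.append(float(row["d_obs_hz"]))
    if len(residues) < 5:
        raise ValueError("need >= 5 RDCs with resolvable N-H vectors")
    vectors = np.asarray(vectors)
    d_obs = np.asarray(d_obs)
    A = _design_matrix(vectors)
    if np.linalg.matrix_rank(A, tol=1e-8) < 5:
        raise ValueError("degenerate bond-vector geometry; tensor under-determined")
    p, *_ = np.linalg.lstsq(A, d_obs, rcond=None)
    tensor = AlignmentTensor(_saupe_from_params(p))
    d_calc = tensor.predict(vectors)
    resid = d_obs - d_calc
    rms = float(np.sqrt(np.mean(resid**2)))
    denom = float(np.sqrt(np.mean(d_obs**2)))
    q = rms / denom if denom > 0 else 0.0
    return TensorFitResult(tensor, np.asarray(residues), d_obs, d_calc, q, rms)


def back_calc_rdc(
    tensor: AlignmentTensor,
    model: StructureModel,
    residues=None,
) -> pd.DataFrame:
    """Predicted N-H couplings per residue; skips residues lacking amides."""
    res, vec = nh_vectors(model, residues=residues)
    if len(res) == 0:
        return pd.DataFrame(columns=["residue", "d_calc_hz"])
    return pd.DataFrame({"residue": res, "d_calc_hz": tensor.predict(vec)})


def compare_domain_tensors(
    rdcs_a: pd.DataFrame | None,
    rdcs_b: pd.DataFrame | None,
    model: StructureModel | None = None,
    da_ratio_tol: float = 0.20,
    ks_level: float = 0.5,
    fits: tuple[TensorFitResult, TensorFitResult] | None = None,
) -> dict:
    """Compare alignment tensors fitted to two domain pairs.

    In a rigid multidomain molecule both pairs share one alignment frame
    and must yield the same tensor; a signed-D_a ratio deviating from 1
    by more than ``da_ratio_tol``, or raw-RDC distributions differing by
    a two-sample Kolmogorov-Smirnov statistic above ``ks_level``, flags
    possible slower-timescale inter-pair mobility.  ``fits`` may supply
    precomputed per-pair fits (e.g. independently published tensors) in
    place of refitting against ``model``; the KS comparison is skipped
    when either raw table is absent.
    """
    if fits is None:
        if rdcs_a is None or rdcs_b is None or model is None:
            raise ValueError("need raw RDC tables and a model, or precomputed fits")
        fit_a = fit_tensor_svd(rdcs_a, model)
        fit_b = fit_tensor_svd(rdcs_b, model)
    else:
        fit_a, fit_b = fits
    if rdcs_a is not None and rdcs_b is not None:
        ks_stat = float(
            stats.ks_2samp(rdcs_a["d_obs_hz"].to_numpy(), rdcs_b["d_obs_hz"].to_numpy()).statistic
        )
    else:
        ks_stat = 0.0
    da_a, da_b = fit_a.d_a, fit_b.d_a
    ratio = da_b / da_a if da_a != 0 else math.inf
    mobility = abs(ratio - 1.0) > da_ratio_tol or ks_stat > ks_level

    def _summary(fit: TensorFitResult) -> dict:
        rng = (
            (float(np.min(fit.d_obs)), float(np.max(fit.d_obs))) if len(fit.d_obs) else (0.0, 0.0)
        )
        return {"d_a": fit.d_a, "rhombicity": fit.rhombicity, "q_factor": fit.q_factor, "range": rng}

    return {
        "pair_a": _summary(fit_a),
        "pair_b": _summary(fit_b),
        "da_ratio": float(ratio),
        "ks_statistic": ks_stat,
        "possible_inter_pair_mobility": bool(mobility),
    }


def read_rdc_table(path) -> pd.DataFrame:
    """Read an RDC TSV with header ``residue d_obs_hz error_hz medium``."""
    df = pd.read_csv(path, sep=r"\s+")
    need = {"residue", "d_obs_hz"}
    if not need.issubset(df.columns):
        raise ValueError(f"RDC table needs columns {sorted(need)}")
    return df
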