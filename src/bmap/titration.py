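"""Chemical-shift-perturbation and peak-broadening analysis of HSQC titrations.

A titration follows amide peaks of a 15N-labeled protein while unlabeled
partner is added.  In fast exchange, peaks shift by the population-
weighted average of free and bound shifts; the per-residue combined
perturbation

    d_comb = sqrt(dH**2 + (dN / 6)**2)

(1H and 15N differences in ppm, the conventional 1/6 nitrogen weight) is
compared against a per-protein threshold.  In intermediate/slow exchange,
binding shows up instead as intensity loss, quantified as the fold-ratio
I0/I_final with a noise-propagated error; peaks that drop below the 3-sigma
detection floor are flagged as vanished and reported as lower bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import DomainMap, StructureEnsemble

#: 15N shift-range weight in the combined CSP
N15_WEIGHT = 6.0

#: default per-protein thresholds (combined shift in ppm, strict >;
#: intensity fold-loss, inclusive >=)
SHIFT_THRESHOLDS = {"FBN1": 0.06, "LTBP1": 0.05}
BROADENING_THRESHOLDS = {"FBN1": 7.0, "LTBP1": 10.0}

#: peaks with final intensity below this multiple of noise are "vanished"
DETECTION_SIGMA = 3.0


@dataclass
class PeakList:
    """Assigned amide peaks at one titration point.

    Arrays are parallel over residues; at most one entry per residue.
    """

    residues: np.ndarray
    h_ppm: np.ndarray
    n_ppm: np.ndarray
    intensity: np.ndarray
    noise: np.ndarray
    ligand_uM: float = 0.0
    protein_uM: float = 300.0

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        for name in ("h_ppm", "n_ppm", "intensity", "noise"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(np.unique(self.residues)) != len(self.residues):
            raise ValueError("duplicate residue in peak list")
        if np.any(self.noise <= 0):
            raise ValueError("noise sigma must be positive")
        if self.ligand_uM < 0 or self.protein_uM < 0:
            raise ValueError("concentrations must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residues,
                "h_ppm": self.h_ppm,
                "n_ppm": self.n_ppm,
                "intensity": self.intensity,
                "noise": self.noise,
            }
        )


@dataclass
class TitrationSeries:
    """Ordered peak lists at strictly increasing ligand concentration."""

    points: list[PeakList]
    labeled_protein: str = "FBN1"
    ligand_protein: str = "LTBP1"

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("empty series")
        concs = [p.ligand_uM for p in self.points]
        if concs[0] != 0:
            raise ValueError("first titration point must have zero ligand")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("ligand concentrations must be strictly increasing")
        first = set(self.points[0].residues.tolist())
        for p in self.points[1:]:
            extra = set(p.residues.tolist()) - first
            if extra:
                raise ValueError(f"residues {sorted(extra)} appear only after the first point")

    @property
    def first(self) -> PeakList:
        return self.points[0]

    @property
    def last(self) -> PeakList:
        return self.points[-1]


def combined_shift(delta_h: float | np.ndarray, delta_n: float | np.ndarray) -> float | np.ndarray:
    """Combined 1H/15N chemical-shift perturbation in ppm."""
    delta_h = np.asarray(delta_h, dtype=float)
    delta_n = np.asarray(delta_n, dtype=float)
    if not (np.all(np.isfinite(delta_h)) and np.all(np.isfinite(delta_n))):
        raise ValueError("non-finite shift difference")
    out = np.sqrt(delta_h**2 + (delta_n / N15_WEIGHT) ** 2)
    return float(out) if out.ndim == 0 else out


def csp_profile(series: TitrationSeries) -> pd.DataFrame:
    """Endpoint-vs-start CSP per residue.

    Residues absent from the final point (broadened away, unassigned)
    are kept with NaN deltas rather than dropped.  Columns: residue,
    d_h, d_n, d_comb, missing.
    """
    if len(series.points) < 2:
        raise ValueError("need at least two titration points")
    p0, pf = series.first, series.last
    if len(p0.residues) == 0:
        raise ValueError("empty residue universe")
    f0 = p0.to_frame().set_index("residue")
    ff = pf.to_frame().set_index("residue")
    rows = []
    for res in f0.index:
        if res in ff.index:
            dh = float(ff.loc[res, "h_ppm"] - f0.loc[res, "h_ppm"])
            dn = float(ff.loc[res, "n_ppm"] - f0.loc[res, "n_ppm"])
            rows.append((res, dh, dn, combined_shift(dh, dn), False))
        else:
            rows.append((res, math.nan, math.nan, math.nan, True))
    return pd.DataFrame(rows, columns=["residue", "d_h", "d_n", "d_comb", "missing"])


def broadening_profile(series: TitrationSeries) -> pd.DataFrame:
    """Fold intensity loss I0/I_final per residue with propagated error.

    ``ratio_err = ratio * sqrt((s0/I0)**2 + (sf/If)**2)``.  Peaks whose
    final intensity falls below ``DETECTION_SIGMA * noise`` (or that
    vanish entirely) get ``vanished=True`` and a lower-bound ratio
    ``I0 / (3 * sigma_f)``.  Columns: residue, ratio, ratio_err, vanished.
    """
    p0, pf = series.first, series.last
    f0 = p0.to_frame().set_index("residue")
    ff = pf.to_frame().set_index("residue")
    rows = []
    for res in f0.index:
        i0 = float(f0.loc[res, "intensity"])
        s0 = float(f0.loc[res, "noise"])
        if i0 <= 0:
            raise ValueError(f"non-positive reference intensity at residue {res}")
        if res in ff.index:
            i_f = float(ff.loc[res, "intensity"])
            s_f = float(ff.loc[res, "noise"])
        else:
            i_f, s_f = 0.0, s0  # peak gone: assume same noise floor
        if i_f < DETECTION_SIGMA * s_f:
            ratio = i0 / (DETECTION_SIGMA * s_f)
            rows.append((res, ratio, math.nan, True))
        else:
            ratio = i0 / i_f
            err = ratio * math.sqrt((s0 / i0) ** 2 + (s_f / i_f) ** 2)
            rows.append((res, ratio, err, False))
    return pd.DataFrame(rows, columns=["residue", "ratio", "ratio_err", "vanished"])


def call_interface(
    profile: pd.DataFrame,
    protein: str | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Call interface residues from a CSP or broadening profile.

    Shift calls are strict (``d_comb > threshold``, "more than"); fold-
    loss calls are inclusive (``ratio >= threshold``, "at least").
    Vanished peaks are always called.  Returns columns: residue,
    mechanism, statistic, threshold, called.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    is_csp = "d_comb" in profile.columns
    if threshold is None:
        table = SHIFT_THRESHOLDS if is_csp else BROADENING_THRESHOLDS
        if protein not in table:
            raise ValueError(f"unknown protein label {protein!r}; pass threshold=")
        threshold = table[protein]
    rows = []
    if is_csp:
        for _, r in profile.iterrows():
            stat = r["d_comb"]
            called = bool(stat > threshold) if np.isfinite(stat) else False
            rows.append((int(r["residue"]), "shift", stat, threshold, called))
    else:
        for _, r in profile.iterrows():
            called = bool(r["vanished"]) or bool(r["ratio"] >= threshold)
            rows.append((int(r["residue"]), "broadening", r["ratio"], threshold, called))
    return pd.DataFrame(rows, columns=["residue", "mechanism", "statistic", "threshold", "called"])


def called_residues(calls: pd.DataFrame) -> list[int]:
    return sorted(calls.loc[calls["called"], "residue"].astype(int).tolist())


def map_calls(
    calls: pd.DataFrame,
    ensemble: StructureEnsemble | None,
    domains: DomainMap,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate calls with domains and summarize per-domain counts.

    Residues outside every domain range (or absent from the structure)
    are listed under the "unmapped" label.  Returns (per-residue
    annotation table, per-domain summary).
    """
    if not domains.ranges:
        raise ValueError("empty domain map")
    structure_residues: set[int] | None = None
    if ensemble is not None:
        structure_residues = set(int(r) for r in ensemble.models[0].res_numbers)
    ann_rows = []
    for _, r in calls.iterrows():
        res = int(r["residue"])
        dom = domains.domain_of(res)
        in_structure = structure_residues is None or res in structure_residues
        ann_rows.append(
            (res, r["mechanism"], bool(r["called"]), dom or "unmapped", in_structure)
        )
    ann = pd.DataFrame(
        ann_rows, columns=["residue", "mechanism", "called", "domain", "in_structure"]
    )
    called = ann[ann["called"]]
    if len(called) == 0:
        summary = pd.DataFrame(columns=["domain", "n_called"])
    else:
        summary = (
            called.groupby("domain").size().reset_index(name="n_called")
            .sort_values("domain").reset_index(drop=True)
        )
    return ann, summary


# ---------------------------------------------------------------------------
# I/O

def read_peak_list(path, ligand_uM: float, protein_uM: float = 300.0) -> PeakList:
    """Read a TSV peak list with header ``residue h_ppm n_ppm intensity noise``."""
    df = pd.read_csv(path, sep=r"\s+")
    need = {"residue", "h_ppm", "n_ppm", "intensity", "noise"}
    if not need.issubset(df.columns):
        raise ValueError(f"peak list needs columns {sorted(need)}")
    return PeakList(
        df["residue"].to_numpy(), df["h_ppm"].to_numpy(), df["n_ppm"].to_numpy(),
        df["intensity"].to_numpy(), df["noise"].to_numpy(),
        ligand_uM=ligand_uM, protein_uM=protein_uM,
    )


def write_peak_list(peaks: PeakList, path) -> None:
    peaks.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
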