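"""Structure ensembles, superposition, precision and geometry scans.

Coordinates live in plain numpy arrays inside :class:`StructureModel`;
multi-model PDB (and read-only mmCIF) I/O goes through gemmi.  Residue
numbers are 1-based and taken verbatim from the coordinate records, and
all residue ranges are inclusive on both ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: default heavy-atom cutoffs, Angstrom
DISULFIDE_CUTOFF = 2.5
SALT_BRIDGE_CUTOFF = 4.0

#: maximally extended span contributed by one linker residue, Angstrom
PER_RESIDUE_EXTENSION = 3.8

_BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass
class StructureModel:
    """One set of atomic coordinates.

    Parallel arrays: ``chains``, ``res_numbers``, ``res_names``,
    ``atom_names``, ``elements`` (length-N object/str arrays) and an
    ``(N, 3)`` float coordinate array in Angstrom.
    """

    chains: np.ndarray
    res_numbers: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    model_id: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        for name in ("chains", "res_numbers", "res_names", "atom_names", "elements"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in model %d" % self.model_id)
        if len(self.coords) != len(self.atom_names):
            raise ValueError("atom annotation/coordinate length mismatch")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def roster(self) -> tuple:
        """Hashable atom roster used to verify ensemble consistency."""
        return tuple(zip(self.chains, self.res_numbers, self.atom_names))

    def select(
        self,
        residues: Sequence[int] | range | None = None,
        atom_names: Iterable[str] | None = None,
        chain: str | None = None,
    ) -> np.ndarray:
        """Boolean mask over atoms for a residue range / atom-name set."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residues is not None:
            mask &= np.isin(self.res_numbers.astype(int), np.asarray(list(residues)))
        if atom_names is not None:
            mask &= np.isin(self.atom_names, np.asarray(list(atom_names)))
        if chain is not None:
            mask &= self.chains == chain
        return mask

    def atom_coord(self, resnum: int, atom_name: str, chain: str | None = None) -> np.ndarray:
        mask = self.select(residues=[resnum], atom_names=[atom_name], chain=chain)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(f"atom {atom_name} of residue {resnum} not found")
        return self.coords[idx[0]]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.chains, self.res_numbers, self.res_names, self.atom_names,
            self.elements, self.coords @ np.asarray(rotation).T + translation,
            self.model_id,
        )


@dataclass
class StructureEnsemble:
    """A family of models sharing one atom roster (an NMR-style bundle)."""

    models: list[StructureModel]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        ref = self.models[0].roster()
        bad = [m.model_id for m in self.models[1:] if m.roster() != ref]
        if bad:
            raise ValueError(f"inconsistent atom rosters in models {bad}")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


@dataclass
class DomainMap:
    """Named inclusive residue ranges, e.g. EGF2-EGF3 = 119-178."""

    ranges: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("empty domain map")
        for name, (lo, hi) in self.ranges.items():
            if hi < lo:
                raise ValueError(f"empty range for domain {name}")

    def domain_of(self, residue: int) -> str | None:
        for name, (lo, hi) in self.ranges.items():
            if lo <= residue <= hi:
                return name
        return None


@dataclass
class ContactHit:
    kind: str  # "disulfide" | "salt-bridge"
    residue_i: tuple[str, int, str]  # (chain, number, name)
    residue_j: tuple[str, int, str]
    atom_i: str
    atom_j: str
    distance: float
    model_id: int = 1


# ---------------------------------------------------------------------------
# I/O

def _model_from_gemmi(gmodel: gemmi.Model, model_id: int) -> StructureModel:
    chains, resnums, resnames, atnames, elements, xyz = [], [], [], [], [], []
    for chain in gmodel:
        for res in chain:
            for atom in res:
                chains.append(chain.name)
                resnums.append(res.seqid.num)
                resnames.append(res.name)
                atnames.append(atom.name)
                elements.append(atom.element.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return StructureModel(
        np.array(chains), np.array(resnums, dtype=int), np.array(resnames),
        np.array(atnames), np.array(elements), np.array(xyz, dtype=float),
        model_id,
    )


def read_ensemble(path: str | Path, fmt: str | None = None) -> StructureEnsemble:
    """Read a (multi-model) PDB or mmCIF file into an ensemble.

    Single-model files yield an ensemble of size 1.  Models with
    mismatched atom rosters are rejected with their ids named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    models = [_model_from_gemmi(m, i + 1) for i, m in enumerate(st)]
    if not models:
        raise ValueError(f"no models found in {path}")
    return StructureEnsemble(models, source=path.name)


def write_ensemble(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write as multi-model PDB (MODEL/ENDMDL)."""
    st = gemmi.Structure()
    st.name = ensemble.source or "bmap"
    for model in ensemble:
        gm = gemmi.Model(model.model_id)
        chain_objs: dict[str, gemmi.Chain] = {}
        prev_key = None
        res_obj = None
        for i in range(model.n_atoms):
            cname = str(model.chains[i])
            if cname not in chain_objs:
                chain_objs[cname] = gemmi.Chain(cname)
                gm.add_chain(chain_objs[cname])
                chain_objs[cname] = gm[cname]
            key = (cname, int(model.res_numbers[i]))
            if key != prev_key:
                res_obj = gemmi.Residue()
                res_obj.name = str(model.res_names[i])
                res_obj.seqid = gemmi.SeqId(int(model.res_numbers[i]), " ")
                gm[cname].add_residue(res_obj)
                res_obj = gm[cname][-1]
                prev_key = key
            atom = gemmi.Atom()
            atom.name = str(model.atom_names[i])
            atom.element = gemmi.Element(str(model.elements[i]))
            atom.pos = gemmi.Position(*model.coords[i])
            res_obj.add_atom(atom)
        st.add_model(gm)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# Superposition and precision

def kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (proper rotation, det = +1).

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best fits the
    reference.
    """
    mobile_xyz = np.asarray(mobile_xyz, float)
    ref_xyz = np.asarray(ref_xyz, float)
    if mobile_xyz.shape != ref_xyz.shape or mobile_xyz.shape[0] < 3:
        raise ValueError("need >= 3 paired atoms of identical shape")
    mc = mobile_xyz.mean(axis=0)
    rc = ref_xyz.mean(axis=0)
    P = mobile_xyz - mc
    Q = ref_xyz - rc
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(P, tol=1e-8) < 2:
        raise ValueError("selection is collinear; superposition is degenerate")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    fitted = mobile_xyz @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref_xyz) ** 2, axis=1))))
    return R, t, rmsd


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    residues: Sequence[int] | range | None = None,
    atom_names: Iterable[str] | None = BACKBONE_ATOMS,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Superpose ``mobile`` onto ``reference`` over a selection."""
    mask_m = mobile.select(residues=residues, atom_names=atom_names)
    mask_r = reference.select(residues=residues, atom_names=atom_names)
    if mask_m.sum() != mask_r.sum() or mask_m.sum() < 3:
        raise ValueError("selection resolves to fewer than 3 paired atoms")
    return kabsch(mobile.coords[mask_m], reference.coords[mask_r])


def ensemble_precision(
    ensemble: StructureEnsemble,
    residues: Sequence[int] | range,
    atom_names: Iterable[str] = BACKBONE_ATOMS,
    tol: float = 1e-4,
    max_iter: int = 100,
    fit_residues: Sequence[int] | range | None = None,
) -> float:
    """Coordinate precision: mean RMSD of each model to the mean structure.

    Models are iteratively superposed on the evolving mean until the
    mean RMSD changes by less than ``tol`` Angstrom.  The superposition
    fit normally uses the reported selection; ``fit_residues`` lets the
    fit run on a different residue set (e.g. to exclude a mobile tail
    from the alignment while still reporting its spread).
    """
    if len(ensemble) < 2:
        raise ValueError("precision needs at least 2 models")
    masks = [m.select(residues=residues, atom_names=atom_names) for m in ensemble]
    n_sel = masks[0].sum()
    if n_sel == 0 or any(m.sum() != n_sel for m in masks):
        raise ValueError("selection absent or inconsistent across models")
    fit_masks = masks if fit_residues is None else [
        m.select(residues=fit_residues, atom_names=atom_names) for m in ensemble
    ]
    clouds = [m.coords[mask].copy() for m, mask in zip(ensemble, masks)]
    fit_clouds = [m.coords[mask].copy() for m, mask in zip(ensemble, fit_masks)]
    prev = math.inf
    rmsd_mean = math.inf
    for _ in range(max_iter):
        fit_mean = np.mean(fit_clouds, axis=0)
        mean = np.mean(clouds, axis=0)
        rmsds = []
        for k in range(len(clouds)):
            R, t, _ = kabsch(fit_clouds[k], fit_mean)
            fit_clouds[k] = fit_clouds[k] @ R.T + t
            clouds[k] = clouds[k] @ R.T + t
            rmsds.append(float(np.sqrt(np.mean(np.sum((clouds[k] - mean) ** 2, axis=1)))))
        rmsd_mean = float(np.mean(rmsds))
        if abs(prev - rmsd_mean) < tol:
            break
        prev = rmsd_mean
    return rmsd_mean


# ---------------------------------------------------------------------------
# Contact scans

def _residue_key(model: StructureModel, i: int) -> tuple[str, int, str]:
    return (str(model.chains[i]), int(model.res_numbers[i]), str(model.res_names[i]))


def scan_contacts(
    model: StructureModel,
    kind: str,
    cutoff: float | None = None,
) -> list[ContactHit]:
    """Find disulfide (SG-SG) or salt-bridge (N-O) contacts.

    Disulfides use greedy nearest-first pairing so each SG joins at most
    one bond; salt bridges report one hit per residue pair at the minimal
    basic-N / acidic-O distance.  Output order is deterministic (sorted
    by residue numbers).
    """
    if kind not in ("disulfide", "salt-bridge"):
        raise ValueError(f"unknown contact kind: {kind}")
    if cutoff is None:
        cutoff = DISULFIDE_CUTOFF if kind == "disulfide" else SALT_BRIDGE_CUTOFF
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    hits: list[ContactHit] = []
    if kind == "disulfide":
        idx = np.flatnonzero((model.res_names == "CYS") & (model.atom_names == "SG"))
        if len(idx) < 2:
            return []
        xyz = model.coords[idx]
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
        pairs = [
            (d[a, b], a, b)
            for a in range(len(idx))
            for b in range(a + 1, len(idx))
            if d[a, b] <= cutoff
        ]
        used: set[int] = set()
        for dist, a, b in sorted(pairs):
            if a in used or b in used:
                continue
            used.update((a, b))
            ia, ib = idx[a], idx[b]
            ri, rj = _residue_key(model, ia), _residue_key(model, ib)
            if rj < ri:
                ri, rj = rj, ri
            hits.append(ContactHit("disulfide", ri, rj, "SG", "SG", float(dist), model.model_id))
    else:
        basic_idx = [
            i for i in range(model.n_atoms)
            if model.atom_names[i] in _BASIC_ATOMS.get(str(model.res_names[i]), ())
        ]
        acidic_idx = [
            i for i in range(model.n_atoms)
            if model.atom_names[i] in _ACIDIC_ATOMS.get(str(model.res_names[i]), ())
        ]
        if not basic_idx or not acidic_idx:
            return []
        bxyz = model.coords[basic_idx]
        axyz = model.coords[acidic_idx]
        d = np.linalg.norm(bxyz[:, None] - axyz[None, :], axis=-1)
        best: dict[tuple, tuple] = {}
        for a, ia in enumerate(basic_idx):
            for b, ib in enumerate(acidic_idx):
                if d[a, b] > cutoff:
                    continue
                key = (_residue_key(model, ia), _residue_key(model, ib))
                cur = best.get(key)
                if cur is None or d[a, b] < cur[0]:
                    best[key] = (d[a, b], str(model.atom_names[ia]), str(model.atom_names[ib]))
        for (ri, rj), (dist, an_i, an_j) in sorted(best.items()):
            hits.append(ContactHit("salt-bridge", ri, rj, an_i, an_j, float(dist), model.model_id))
    hits.sort(key=lambda h: (h.residue_i, h.residue_j))
    return hits


def linker_span_feasible(
    anchor_a: np.ndarray,
    anchor_b: np.ndarray,
    n_linker_residues: int,
    per_residue_extension: float = PER_RESIDUE_EXTENSION,
) -> tuple[float, float, bool]:
    """Can an ``n``-residue flexible linker bridge two anchor points?

    Returns ``(span, max_reach, feasible)`` with ``max_reach = n * per-
    residue extension`` (3.8 Angstrom/residue, a fully extended chain).
    """
    if n_linker_residues < 0:
        raise ValueError("negative linker length")
    span = float(np.linalg.norm(np.asarray(anchor_a, float) - np.asarray(anchor_b, float)))
    max_reach = n_linker_residues * per_residue_extension
    return span, max_reach, span <= max_reach


# ---------------------------------------------------------------------------
# Restraint accounting

NOE_CATEGORIES = ("intra", "sequential", "short", "long", "ambiguous")
ALL_CATEGORIES = NOE_CATEGORIES + ("hbond", "dihedral", "rdc")


def classify_noe(res_i: int, res_j: int) -> str:
    """Category of an unambiguous NOE from sequence separation |i-j|."""
    sep = abs(int(res_i) - int(res_j))
    if sep == 0:
        return "intra"
    if sep == 1:
        return "sequential"
    if sep < 5:
        return "short"
    return "long"


def read_restraint_table(path: str | Path) -> pd.DataFrame:
    """Read a restraint TSV with header ``res_i res_j upper category``."""
    df = pd.read_csv(path, sep=r"\s+")
    expected = {"res_i", "res_j", "upper", "category"}
    if not expected.issubset(df.columns):
        raise ValueError(f"restraint table needs columns {sorted(expected)}")
    return df


def summarize_restraints(table: pd.DataFrame) -> dict[str, int]:
    """Count restraints per category and derive the standard totals.

    Totals obey: unambiguous = intra + inter, inter = sequential + short
    + long, total_noe = unambiguous + ambiguous.
    """
    counts = {c: 0 for c in ALL_CATEGORIES}
    for cat, n in table["category"].value_counts().items():
        if cat not in counts:
            raise ValueError(f"unknown restraint category: {cat}")
        counts[cat] = int(n)
    inter = counts["sequential"] + counts["short"] + counts["long"]
    unambiguous = counts["intra"] + inter
    counts["inter"] = inter
    counts["unambiguous"] = unambiguous
    counts["total_noe"] = unambiguous + counts["ambiguous"]
    return counts
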