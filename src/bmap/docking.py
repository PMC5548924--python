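"""Restraint-driven rigid-body docking of a bipartite complex.

Interface calls from the titration analysis become ambiguous
interaction restraints (AIRs): each *active* residue of one molecule is
restrained to the union of active + passive residues of the partner
through the r^-6-summed effective distance

    d_eff = ( sum over atom pairs d^-6 )^(-1/6),

which is satisfied (no penalty) once d_eff falls below a ceiling
(default 2.0 Angstrom).  A desk-scale Monte-Carlo search samples rigid
placements of the mobile molecule, excludes a random fraction of the
AIRs each trial (guarding against individual wrong calls), locally
refines the six rigid degrees of freedom against a quadratic restraint
energy, and ranks poses.  This replaces flexible docking machinery: the
questions asked of the models here — which faces pair, which salt
bridges are plausible, whether a linker can span the two sub-complexes
— are answerable at rigid-body resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structures import (
    StructureModel,
    linker_span_feasible,
    scan_contacts,
)

AIR_CEILING = 2.0
#: effective-distance ceiling suited to one-bead-per-residue models,
#: whose closest approach across a contact is one CA-CA van der Waals
#: gap (~4.5 A) rather than the ~2 A of touching all-atom side chains
BEAD_AIR_CEILING = 5.5
AIR_EXCLUSION_FRACTION = 0.10
AIR_PARTITIONS = 10
NEIGHBOR_RADIUS = 6.5
CLASH_DISTANCE = 2.8
#: CA-CA separations below ~3.5 A do not occur between non-bonded
#: residues, so this is the clash criterion for bead-per-residue models
BEAD_CLASH_DISTANCE = 3.5
#: the soft refinement wall begins this far outside the clash distance,
#: so refined poses settle just clear of the hard clash count
SOFT_CLASH_MARGIN = 0.25
#: poses whose scores differ by less than this are ranked by interface
#: tightness instead (sub-resolution restraint-violation differences)
SCORE_TIE_QUANTUM = 0.01
SALT_BRIDGE_CEILING = 4.0

DEFAULT_WEIGHTS = {"air": 1.0, "saltbridge": 1.0, "clash": 0.1}


@dataclass
class AirRestraintSet:
    """Active/passive residue sets defining ambiguous restraints."""

    active_static: list[int]
    passive_static: list[int]
    active_mobile: list[int]
    passive_mobile: list[int]
    ceiling: float = AIR_CEILING
    exclusion_fraction: float = AIR_EXCLUSION_FRACTION
    n_partitions: int = AIR_PARTITIONS

    def __post_init__(self) -> None:
        if set(self.active_static) & set(self.passive_static):
            raise ValueError("active and passive overlap on the static molecule")
        if set(self.active_mobile) & set(self.passive_mobile):
            raise ValueError("active and passive overlap on the mobile molecule")
        if not 0 <= self.exclusion_fraction < 1:
            raise ValueError("exclusion fraction must be in [0, 1)")

    @property
    def n_restraints(self) -> int:
        return len(self.active_static) + len(self.active_mobile)

    def exclusion_count(self) -> int:
        """Restraints removed per trial: ceil(fraction * N)."""
        return math.ceil(self.exclusion_fraction * self.n_restraints)


@dataclass
class SaltBridgeRestraint:
    basic_residue: int  # on the static molecule by convention
    acidic_residue: int  # on the mobile molecule
    ceiling: float = SALT_BRIDGE_CEILING


@dataclass
class DockingPose:
    rotation: np.ndarray
    translation: np.ndarray
    score: float
    air_energy: float
    saltbridge_energy: float
    clash_count: int
    trial: int
    seed: int
    excluded: tuple[int, ...] = ()
    #: mean AIR effective distance; breaks score ties in favour of the
    #: tighter (better shape-complementary) interface
    mean_d_eff: float = 0.0


@dataclass
class LinkerSpec:
    """Flexible linker between residues of two placed bodies."""

    body_a: str
    residue_a: int
    body_b: str
    residue_b: int
    n_residues: int


@dataclass
class ComplexAssembly:
    linker_verdicts: list[dict]
    inter_body_clashes: int
    valid: bool


# ---------------------------------------------------------------------------
# AIR derivation and effective distance

def heavy_mask(model: StructureModel) -> np.ndarray:
    return model.elements != "H"


def derive_airs(
    calls_static: list[int],
    calls_mobile: list[int],
    static: StructureModel,
    mobile: StructureModel,
    neighbor_radius: float = NEIGHBOR_RADIUS,
    **kwargs,
) -> AirRestraintSet:
    """Active residues = interface calls; passive = their surface shell.

    A residue is passive when any of its heavy atoms lies within
    ``neighbor_radius`` of a heavy atom of an active residue of the same
    molecule (and is not itself active).  Deterministic.
    """
    if not calls_static or not calls_mobile:
        raise ValueError("need at least one called residue on each molecule")

    def passives(model: StructureModel, active: list[int]) -> list[int]:
        hm = heavy_mask(model)
        act_mask = hm & np.isin(model.res_numbers.astype(int), active)
        if not act_mask.any():
            raise ValueError("active residues not present in the model")
        other_mask = hm & ~np.isin(model.res_numbers.astype(int), active)
        if not other_mask.any():
            return []
        d = cdist(model.coords[other_mask], model.coords[act_mask])
        near = d.min(axis=1) <= neighbor_radius
        return sorted(set(model.res_numbers[other_mask][near].astype(int).tolist()))

    return AirRestraintSet(
        active_static=sorted(set(calls_static)),
        passive_static=passives(static, sorted(set(calls_static))),
        active_mobile=sorted(set(calls_mobile)),
        passive_mobile=passives(mobile, sorted(set(calls_mobile))),
        **kwargs,
    )


def air_effective_distance(coords_active: np.ndarray, coords_partner: np.ndarray) -> float:
    """r^-6-summed effective distance between two atom groups."""
    coords_active = np.atleast_2d(coords_active)
    coords_partner = np.atleast_2d(coords_partner)
    if len(coords_active) == 0 or len(coords_partner) == 0:
        raise ValueError("no atom pairs")
    d = cdist(coords_active, coords_partner)
    return float(np.sum(d**-6.0) ** (-1.0 / 6.0))


# ---------------------------------------------------------------------------
# Energy model

class _DockingProblem:
    """Precomputed atom indexing for fast energy evaluation."""

    def __init__(
        self,
        static: StructureModel,
        mobile: StructureModel,
        airs: AirRestraintSet,
        saltbridges: list[SaltBridgeRestraint],
        weights: dict | None = None,
        flexible_static: list[int] | None = None,
        flexible_mobile: list[int] | None = None,
        clash_distance: float = CLASH_DISTANCE,
    ):
        self.static = static
        self.mobile = mobile
        self.airs = airs
        self.saltbridges = saltbridges or []
        self.clash_distance = clash_distance
        self.w = dict(DEFAULT_WEIGHTS)
        if weights:
            self.w.update(weights)

        hs = heavy_mask(static)
        hmb = heavy_mask(mobile)
        self.static_xyz = static.coords[hs]
        self.static_res = static.res_numbers[hs].astype(int)
        self.mobile_xyz0 = mobile.coords[hmb]
        self.mobile_res = mobile.res_numbers[hmb].astype(int)

        # atoms excluded from the clash term (declared flexible segments)
        fs = np.isin(self.static_res, flexible_static or [])
        fm = np.isin(self.mobile_res, flexible_mobile or [])
        self.static_clash = ~fs
        self.mobile_clash = ~fm

        partner_static = np.flatnonzero(
            np.isin(self.static_res, airs.active_static + airs.passive_static)
        )
        partner_mobile = np.flatnonzero(
            np.isin(self.mobile_res, airs.active_mobile + airs.passive_mobile)
        )
        # flattened (static atom, mobile atom, restraint id) pair lists so a
        # single gather + bincount evaluates every AIR effective distance
        rows, cols, rid = [], [], []
        self.n_restraints = 0
        for res in airs.active_static:
            ai = np.flatnonzero(self.static_res == res)
            if len(ai) and len(partner_mobile):
                r, c = np.meshgrid(ai, partner_mobile, indexing="ij")
                rows.append(r.ravel())
                cols.append(c.ravel())
                rid.append(np.full(r.size, self.n_restraints))
                self.n_restraints += 1
        for res in airs.active_mobile:
            ai = np.flatnonzero(self.mobile_res == res)
            if len(ai) and len(partner_static):
                r, c = np.meshgrid(partner_static, ai, indexing="ij")
                rows.append(r.ravel())
                cols.append(c.ravel())
                rid.append(np.full(r.size, self.n_restraints))
                self.n_restraints += 1
        if self.n_restraints:
            self.air_rows = np.concatenate(rows)
            self.air_cols = np.concatenate(cols)
            self.air_rid = np.concatenate(rid)
        else:
            self.air_rows = self.air_cols = self.air_rid = np.empty(0, dtype=int)

        self.sb_atoms: list[tuple[np.ndarray, np.ndarray]] = []
        for sb in self.saltbridges:
            si = np.flatnonzero(self.static_res == sb.basic_residue)
            mi = np.flatnonzero(self.mobile_res == sb.acidic_residue)
            if len(si) and len(mi):
                self.sb_atoms.append((si, mi))

        self.active_static_centroid = self.static_xyz[
            np.isin(self.static_res, airs.active_static)
        ].mean(axis=0)
        mob_act = self.mobile_xyz0[np.isin(self.mobile_res, airs.active_mobile)]
        self.mobile_active_centroid0 = mob_act.mean(axis=0)
        self.mobile_centroid0 = self.mobile_xyz0.mean(axis=0)
        # outward normals of the two called surfaces, for face-to-face
        # trial initialization
        sn = self.active_static_centroid - self.static_xyz.mean(axis=0)
        self.static_patch_normal = sn / max(np.linalg.norm(sn), 1e-9)
        mn = self.mobile_active_centroid0 - self.mobile_centroid0
        self.mobile_patch_normal0 = mn / max(np.linalg.norm(mn), 1e-9)

    def mobile_placed(self, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
        return self.mobile_xyz0 @ rotation.T + translation

    def energies(
        self,
        rotation: np.ndarray,
        translation: np.ndarray,
        retained: np.ndarray,
        soft_clash: bool = False,
    ) -> tuple[float, float, float, float]:
        """(air, saltbridge, clash, mean_d_eff) terms for a placement.

        ``soft_clash`` swaps the clash count for a quadratic overlap
        penalty, used during gradient-free refinement.  ``mean_d_eff``
        (over retained restraints) is not part of the ranked score; it
        serves as the tightness tie-break and, weakly weighted, as the
        attractive component during refinement.
        """
        mob = self.mobile_placed(rotation, translation)
        d = cdist(self.static_xyz, mob)

        if self.n_restraints:
            d2 = d[self.air_rows, self.air_cols]
            sums = np.bincount(self.air_rid, weights=d2**-6.0,
                               minlength=self.n_restraints)
            d_eff = sums ** (-1.0 / 6.0)
            excess = np.maximum(0.0, d_eff - self.airs.ceiling)
            e_air = float(np.sum((excess * retained) ** 2))
            mean_d_eff = float(np.mean(d_eff[retained])) if retained.any() else 0.0
        else:
            e_air = 0.0
            mean_d_eff = 0.0

        e_sb = 0.0
        for si, mi in self.sb_atoms:
            d_no = float(d[np.ix_(si, mi)].min())
            excess = d_no - SALT_BRIDGE_CEILING
            if excess > 0:
                e_sb += excess * excess

        dc = d[np.ix_(self.static_clash, self.mobile_clash)]
        if soft_clash:
            # stiff quadratic wall: refinement must not buy contact
            # tightness with interpenetration
            overlap = np.maximum(0.0, self.clash_distance + SOFT_CLASH_MARGIN - dc)
            e_clash = 10.0 * float(np.sum(overlap**2))
        else:
            e_clash = float(np.count_nonzero(dc < self.clash_distance))
        return e_air, e_sb, e_clash, mean_d_eff

    def score(self, rotation, translation, retained, soft_clash=False) -> float:
        ea, es, ec, _ = self.energies(rotation, translation, retained, soft_clash)
        return self.w["air"] * ea + self.w["saltbridge"] * es + self.w["clash"] * ec


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform rotation via a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def dock(
    static: StructureModel,
    mobile: StructureModel,
    airs: AirRestraintSet,
    saltbridges: list[SaltBridgeRestraint] | None = None,
    n_trials: int = 1000,
    seed: int = 0,
    weights: dict | None = None,
    flexible_static: list[int] | None = None,
    flexible_mobile: list[int] | None = None,
    refine_maxiter: int = 120,
    clash_distance: float = CLASH_DISTANCE,
) -> list[DockingPose]:
    """Rigid-body AIR-driven docking; returns poses ranked by score.

    Odd trials draw a uniform random orientation; even trials start
    face-to-face (the mobile called-surface normal anti-aligned with
    the static patch normal, random spin and a small random tilt).
    Every trial places the mobile called-surface centroid near the
    static one with a random offset, excludes ``ceil(fraction * N)``
    randomly chosen AIRs, then refines the six rigid degrees of freedom
    (rotation vector + translation) with a derivative-free local
    minimization of the soft-clash energy.  Deterministic for a fixed
    seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if airs.n_restraints == 0:
        raise ValueError("refusing unguided docking: no AIR restraints")
    prob = _DockingProblem(static, mobile, airs, saltbridges or [], weights,
                           flexible_static, flexible_mobile, clash_distance)
    rng = np.random.default_rng(seed)
    n_air = prob.n_restraints
    n_excl = min(airs.exclusion_count(), max(0, n_air - 1))
    poses: list[DockingPose] = []
    for trial in range(n_trials):
        if trial % 2 == 0:
            # face-to-face: map the mobile patch normal onto the
            # inverted static patch normal, spin freely about it, tilt a
            # little
            align, _ = Rotation.align_vectors(
                -prob.static_patch_normal[None, :],
                prob.mobile_patch_normal0[None, :])
            spin = Rotation.from_rotvec(
                rng.uniform(0.0, 2.0 * np.pi) * prob.static_patch_normal)
            tilt = Rotation.from_rotvec(rng.normal(0.0, 0.15, 3))
            R0 = (tilt * spin * align).as_matrix()
        else:
            R0 = _random_rotation(rng)
        # aim the (rotated) mobile active surface at the static one
        target = prob.active_static_centroid + rng.normal(0, 3.0, 3)
        t0 = target - R0 @ prob.mobile_active_centroid0
        retained = np.ones(n_air, dtype=bool)
        if n_excl > 0:
            retained[rng.choice(n_air, size=n_excl, replace=False)] = False

        rv0 = Rotation.from_matrix(R0).as_rotvec()

        def objective(p):
            R = Rotation.from_rotvec(p[:3]).as_matrix()
            ea, es, ec, md = prob.energies(R, p[3:], retained, soft_clash=True)
            # weak attraction (mean d_eff) guides refinement through the
            # flat region where every restraint is already satisfied
            return (prob.w["air"] * ea + prob.w["saltbridge"] * es
                    + prob.w["clash"] * ec + 0.3 * md)

        res = minimize(
            objective,
            np.concatenate([rv0, t0]),
            method="Powell",
            options={"maxiter": refine_maxiter, "xtol": 1e-3, "ftol": 1e-6},
        )

        R = Rotation.from_rotvec(res.x[:3]).as_matrix()
        t = res.x[3:]
        # the attractive stage may press the pose marginally into the
        # hard clash zone; back off along the interface normal, keeping
        # the registration, until the clash count clears (<= 1 A total)
        normal = (prob.mobile_placed(R, t).mean(axis=0)
                  - prob.active_static_centroid)
        nn = np.linalg.norm(normal)
        if nn > 0:
            normal = normal / nn
            for step in range(21):
                _, _, ec_probe, _ = prob.energies(R, t + 0.05 * step * normal,
                                                  retained, soft_clash=False)
                if ec_probe == 0:
                    t = t + 0.05 * step * normal
                    break
        ea, es, ec, md = prob.energies(R, t, retained, soft_clash=False)
        score = prob.w["air"] * ea + prob.w["saltbridge"] * es + prob.w["clash"] * ec
        poses.append(DockingPose(R, t, score, ea, es, int(ec), trial, seed,
                                 tuple(np.flatnonzero(~retained).tolist()), md))
    # scores differing by less than the quantum correspond to restraint
    # violations far below coordinate resolution; such near-ties are
    # settled by interface tightness (mean effective distance)
    poses.sort(key=lambda p: (math.floor(p.score / SCORE_TIE_QUANTUM),
                              p.mean_d_eff, p.trial))
    return poses


def pose_model(mobile: StructureModel, pose: DockingPose) -> StructureModel:
    """The mobile molecule placed by a pose (static frame)."""
    return mobile.transformed(pose.rotation, pose.translation)


def interface_rmsd(
    pose: DockingPose,
    mobile: StructureModel,
    reference_mobile: StructureModel,
    static: StructureModel,
    radius: float = 10.0,
) -> float:
    """RMSD of the mobile interface to its reference placement.

    Both placements live in the static frame (no re-superposition
    needed); the interface is every mobile heavy atom within ``radius``
    of the static molecule in the reference pose.
    """
    hm = heavy_mask(reference_mobile)
    hs = heavy_mask(static)
    ref_xyz = reference_mobile.coords[hm]
    d = cdist(ref_xyz, static.coords[hs])
    iface = d.min(axis=1) <= radius
    if not iface.any():
        iface = np.ones(len(ref_xyz), dtype=bool)
    posed = pose_model(mobile, pose).coords[hm]
    return float(np.sqrt(np.mean(np.sum((posed[iface] - ref_xyz[iface]) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Pose screening and assembly

def _merge_two_chains(static: StructureModel, mobile_placed: StructureModel) -> StructureModel:
    """Combined model with the mobile molecule forced onto chain 'Z'."""
    return StructureModel(
        np.concatenate([static.chains, np.full(mobile_placed.n_atoms, "Z")]),
        np.concatenate([static.res_numbers, mobile_placed.res_numbers]),
        np.concatenate([static.res_names, mobile_placed.res_names]),
        np.concatenate([static.atom_names, mobile_placed.atom_names]),
        np.concatenate([static.elements, mobile_placed.elements]),
        np.vstack([static.coords, mobile_placed.coords]),
    )


def screen_salt_bridges(
    poses: list[DockingPose],
    static: StructureModel,
    mobile: StructureModel,
    top_k: int | None = None,
    cutoff: float = SALT_BRIDGE_CEILING,
    candidates: tuple[list[int], list[int]] | None = None,
) -> pd.DataFrame:
    """Frequency of inter-molecular salt bridges across the top poses.

    ``candidates`` optionally restricts to (basic residues on static,
    acidic residues on mobile).  Columns: basic_res, acidic_res, count,
    frequency; sorted by descending count then residue numbers.
    """
    if not poses:
        raise ValueError("no poses to screen")
    if top_k is None or top_k > len(poses):
        top_k = len(poses)
    counts: dict[tuple[int, int], int] = {}
    for pose in poses[:top_k]:
        merged = _merge_two_chains(static, pose_model(mobile, pose))
        for hit in scan_contacts(merged, "salt-bridge", cutoff=cutoff):
            ci, cj = hit.residue_i[0], hit.residue_j[0]
            if ci == cj or "Z" not in (ci, cj):
                continue  # intra-molecular
            if hit.residue_i[0] == "Z":
                acidic_or_basic_mobile, other = hit.residue_i, hit.residue_j
            else:
                acidic_or_basic_mobile, other = hit.residue_j, hit.residue_i
            # orient the pair as (static residue, mobile residue)
            key = (other[1], acidic_or_basic_mobile[1])
            if candidates is not None:
                if key[0] not in candidates[0] or key[1] not in candidates[1]:
                    continue
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"basic_res": k[0], "acidic_res": k[1], "count": v, "frequency": v / top_k}
        for k, v in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["basic_res", "acidic_res", "count", "frequency"])
    if len(df):
        df = df.sort_values(
            ["count", "basic_res", "acidic_res"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df


def assemble_complex(
    static: StructureModel,
    mobile_a: StructureModel,
    pose_a: DockingPose,
    mobile_b: StructureModel,
    pose_b: DockingPose,
    linkers: list[LinkerSpec],
    clash_ceiling: int = 5,
    per_residue_extension: float = 3.8,
) -> ComplexAssembly:
    """Splice two independently docked sub-complexes in the static frame.

    Both poses must reference the same static molecule.  Each linker is
    checked for span feasibility between its anchor residues; the
    assembly is valid when every linker is feasible and the two placed
    mobile bodies clash in fewer than ``clash_ceiling`` heavy-atom
    pairs.
    """
    placed = {
        "static": static,
        "mobile_a": pose_model(mobile_a, pose_a),
        "mobile_b": pose_model(mobile_b, pose_b),
    }

    def anchor(body: str, residue: int) -> np.ndarray:
        model = placed[body]
        mask = model.res_numbers.astype(int) == residue
        if not mask.any():
            raise KeyError(f"anchor residue {residue} absent from {body}")
        names = model.atom_names[mask]
        if "CA" in names:
            return model.coords[mask][names == "CA"][0]
        return model.coords[mask].mean(axis=0)

    verdicts = []
    for lk in linkers:
        span, reach, ok = linker_span_feasible(
            anchor(lk.body_a, lk.residue_a),
            anchor(lk.body_b, lk.residue_b),
            lk.n_residues,
            per_residue_extension,
        )
        verdicts.append(
            {"linker": f"{lk.body_a}:{lk.residue_a}-{lk.body_b}:{lk.residue_b}",
             "n_residues": lk.n_residues, "span_A": span, "max_reach_A": reach,
             "feasible": ok}
        )
    a_xyz = placed["mobile_a"].coords[heavy_mask(mobile_a)]
    b_xyz = placed["mobile_b"].coords[heavy_mask(mobile_b)]
    clashes = int(np.count_nonzero(cdist(a_xyz, b_xyz) < CLASH_DISTANCE))
    valid = all(v["feasible"] for v in verdicts) and clashes < clash_ceiling
    return ComplexAssembly(verdicts, clashes, valid)


# ---------------------------------------------------------------------------
# I/O

def read_air_table(path) -> dict:
    """AIR TSV with header ``molecule residue role`` (role: active|passive)."""
    df = pd.read_csv(path, sep=r"\s+")
    need = {"molecule", "residue", "role"}
    if not need.issubset(df.columns):
        raise ValueError(f"AIR table needs columns {sorted(need)}")
    out: dict[str, dict[str, list[int]]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["molecule"]), {"active": [], "passive": []})[
            str(r["role"])
        ].append(int(r["residue"]))
    return out


def poses_to_table(poses: list[DockingPose]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"rank": i + 1, "trial": p.trial, "score": p.score, "air": p.air_energy,
             "saltbridge": p.saltbridge_energy, "clashes": p.clash_count, "seed": p.seed}
            for i, p in enumerate(poses)
        ]
    )
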