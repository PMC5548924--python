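"""Synthetic ground-truth data for every stage of the pipeline.

The generator emulates the study design around a bipartite modular-
protein interaction: a 15N-labeled receptor fragment at 300 uM titrated
with 0-250 uM of unlabeled single-site ligand fragments, one site in
fast exchange (K_d ~ 100 uM, peaks shift) and one in intermediate/slow
exchange (K_d ~ 300 uM, peaks broaden); RDCs from known alignment
tensors with 2-4 Hz noise; SAXS curves with multiplicative noise; and
saturable binding assays with a linear nonspecific background.

Molecules are compact one-bead-per-residue lattice lobes (CA atoms on a
3.8 Angstrom snake path), which gives connected, self-avoiding, roughly
globular bodies with well-defined contact faces — enough geometry for
interface mapping, AIR derivation, rigid-body docking and Debye
back-calculation, while carrying none of the side-chain detail of real
domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .docking import DockingPose, LinkerSpec
from .rdc import AlignmentTensor, back_calc_rdc
from .saxs import ScatteringCurve, debye_curve
from .binding import BindingCurve, avidity_apparent_kd, one_site_total
from .structures import StructureModel
from .titration import PeakList, TitrationSeries

import pandas as pd

LATTICE_SPACING = 3.8  # Angstrom, CA-CA


@dataclass
class SimConfig:
    """Experimental design knobs shared by the generators."""

    protein_uM: float = 300.0
    ligand_ladder_uM: tuple = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0)
    shift_noise_h_ppm: float = 0.003
    shift_noise_n_ppm: float = 0.02
    intensity_noise_frac: float = 0.02
    rdc_noise_hz: float = 3.0
    saxs_noise_frac: float = 0.05
    binding_noise_frac: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        ladder = tuple(self.ligand_ladder_uM)
        if ladder[0] != 0 or any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("ligand ladder must start at 0 and increase")
        for name in ("shift_noise_h_ppm", "shift_noise_n_ppm", "intensity_noise_frac",
                     "rdc_noise_hz", "saxs_noise_frac", "binding_noise_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """A synthetic bipartite complex with every generating parameter."""

    static: StructureModel
    mobile_a: StructureModel  # strong site, fast exchange
    mobile_b: StructureModel  # weak site, intermediate/slow exchange
    interface_static_a: list[int]
    interface_mobile_a: list[int]
    interface_static_b: list[int]
    interface_mobile_b: list[int]
    kd_a_uM: float = 100.0
    kd_b_uM: float = 300.0
    dmax_h: dict = field(default_factory=dict)  # residue -> max 1H shift, ppm
    dmax_n: dict = field(default_factory=dict)  # residue -> max 15N shift, ppm
    broadening_beta: dict = field(default_factory=dict)  # residue -> beta
    tensors: dict = field(default_factory=dict)  # domain-pair label -> AlignmentTensor
    linker: LinkerSpec | None = None
    seed: int = 0
    salt_bridges: list = field(default_factory=list)  # (basic static res, acidic mobile res)

    def reference_pose(self) -> DockingPose:
        """Ground-truth placement: the mobile bodies are built docked."""
        return DockingPose(np.eye(3), np.zeros(3), 0.0, 0.0, 0.0, 0, -1, -1)


# ---------------------------------------------------------------------------
# Toy structures

def _snake_lattice(n: int, shape: tuple[int, int, int]) -> np.ndarray:
    """First ``n`` points of a boustrophedon path through a lattice block."""
    nx, ny, nz = shape
    pts = []
    for k in range(nz):
        for j in range(ny):
            jj = j if k % 2 == 0 else ny - 1 - j
            for i in range(nx):
                ii = i if (j + k) % 2 == 0 else nx - 1 - i
                pts.append((ii, jj, k))
                if len(pts) == n:
                    return np.asarray(pts, float) * LATTICE_SPACING
    raise ValueError("lattice too small for chain length")


def make_lobe(
    n_residues: int,
    first_residue: int,
    chain: str = "A",
    shape: tuple[int, int, int] = (4, 4, 4),
    origin: np.ndarray | None = None,
    rotation: np.ndarray | None = None,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> StructureModel:
    """Compact bead-per-residue lobe (ALA CA atoms on a lattice path).

    ``jitter`` adds seeded Gaussian displacement to each bead, giving
    the irregular surface real domains have; without it the lattice
    faces carry artificial rotational symmetry.
    """
    xyz = _snake_lattice(n_residues, shape)
    if jitter > 0:
        rng = rng or np.random.default_rng(0)
        xyz = xyz + rng.normal(0.0, jitter, xyz.shape)
    if rotation is not None:
        xyz = xyz @ np.asarray(rotation, float).T
    if origin is not None:
        xyz = xyz + np.asarray(origin, float)
    n = n_residues
    return StructureModel(
        np.full(n, chain), np.arange(first_residue, first_residue + n),
        np.full(n, "ALA"), np.full(n, "CA"), np.full(n, "C"), xyz,
    )


def make_nh_model(
    n_residues: int,
    seed: int = 0,
    first_residue: int = 1,
    chain: str = "A",
) -> StructureModel:
    """Toy backbone with explicit amide N-H pairs at random orientations.

    Used wherever an RDC calculation needs resolvable bond vectors: N
    atoms sit on a loose spiral, each with an H 1.02 Angstrom away along
    an isotropically random direction.
    """
    rng = np.random.default_rng(seed)
    chains, resnums, resnames, atnames, elements, xyz = [], [], [], [], [], []
    for k in range(n_residues):
        theta = 0.6 * k
        n_pos = np.array([8.0 * math.cos(theta), 8.0 * math.sin(theta), 1.5 * k])
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        h_pos = n_pos + 1.02 * v
        for name, el, pos in (("N", "N", n_pos), ("H", "H", h_pos)):
            chains.append(chain)
            resnums.append(first_residue + k)
            resnames.append("ALA")
            atnames.append(name)
            elements.append(el)
            xyz.append(pos)
    return StructureModel(
        np.array(chains), np.array(resnums, dtype=int), np.array(resnames),
        np.array(atnames), np.array(elements), np.array(xyz, dtype=float),
    )


def _contact_residues(a: StructureModel, b: StructureModel, radius: float = 6.0):
    d = cdist(a.coords, b.coords)
    ia = sorted(set(a.res_numbers[(d.min(axis=1) <= radius)].astype(int).tolist()))
    ib = sorted(set(b.res_numbers[(d.min(axis=0) <= radius)].astype(int).tolist()))
    return ia, ib


def _dock_against(lobe: StructureModel, static: StructureModel,
                  direction: np.ndarray, gap: float) -> StructureModel:
    """Translate a lobe along ``direction`` until its closest heavy-atom
    approach to the static body equals ``gap`` (bisection)."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    base = lobe.coords - lobe.coords.mean(axis=0) + static.coords.mean(axis=0)
    lo, hi = 0.0, 300.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if cdist(base + mid * d, static.coords).min() < gap:
            lo = mid
        else:
            hi = mid
    return StructureModel(lobe.chains, lobe.res_numbers, lobe.res_names,
                          lobe.atom_names, lobe.elements, base + hi * d)


def _mold_contact(static: StructureModel, n_contact: int = 12,
                  standoff: float = 3.55, direction: int = +1) -> np.ndarray:
    """Bead positions molded into the hollows of a jittered surface.

    Candidate points on a fine lateral grid are slid along +-x until
    their closest approach to the static body equals ``standoff``; the
    ``n_contact`` points touching the most static beads are kept
    greedily, at least one bead diameter apart.  Because the jittered
    surface is aperiodic, the resulting contact layer nests against it
    in a unique registration — the lock-and-key complementarity real
    interfaces have.
    """
    xyz = static.coords
    x_edge = xyz[:, 0].max() if direction > 0 else xyz[:, 0].min()
    lo_y, hi_y = xyz[:, 1].min() - 1.0, xyz[:, 1].max() + 1.0
    lo_z, hi_z = xyz[:, 2].min() - 1.0, xyz[:, 2].max() + 1.0
    cands = []
    for y in np.arange(lo_y, hi_y, 1.1):
        for z in np.arange(lo_z, hi_z, 1.1):
            lo, hi = 0.0, 25.0
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                p = [[x_edge + direction * mid, y, z]]
                if cdist(p, xyz).min() < standoff:
                    lo = mid
                else:
                    hi = mid
            p = np.array([x_edge + direction * hi, y, z])
            score = int(np.count_nonzero(cdist([p], xyz) <= 4.3))
            cands.append((score, -hi, tuple(p)))
    cands.sort(reverse=True)
    chosen: list[np.ndarray] = []
    for _, _, p in cands:
        p = np.array(p)
        if all(np.linalg.norm(p - q) >= 3.5 for q in chosen):
            chosen.append(p)
        if len(chosen) == n_contact:
            break
    return np.asarray(chosen)


def _make_molded_mobile(static: StructureModel, first_residue: int, chain: str,
                        rng: np.random.Generator, direction: int = +1,
                        n_contact: int = 12) -> StructureModel:
    """A 36-bead ligand lobe whose contact layer complements the static
    surface, backed by two jittered 4x3 lattice layers."""
    contact = _mold_contact(static, n_contact=n_contact, direction=direction)
    x0 = contact[:, 0].mean()
    y0 = static.coords[:, 1].mean() - 1.8 * 3.0
    z0 = static.coords[:, 2].mean() - 1.8 * 2.0
    back = np.array([
        [x0 + direction * LATTICE_SPACING * layer, y0 + 3.6 * j, z0 + 3.6 * k]
        for layer in (1, 2) for j in range(4) for k in range(3)
    ])
    back = back + rng.normal(0.0, 0.4, back.shape)
    xyz = np.vstack([contact, back])
    n = len(xyz)
    return StructureModel(
        np.full(n, chain), np.arange(first_residue, first_residue + n),
        np.full(n, "ALA"), np.full(n, "CA"), np.full(n, "C"), xyz,
    )


def _add_salt_bridge_markers(static: StructureModel, mobile: StructureModel,
                             n_pairs: int = 2, max_no: float = 4.0):
    """Recast the closest contact-bead pairs as ARG/ASP with guanidinium
    and carboxylate marker atoms at the bead positions.

    Returns (static', mobile', [(basic residue, acidic residue)]).  The
    marker atoms coincide with their CA beads, so the docking geometry
    is unchanged while salt-bridge scans see real N-O pairs.
    """
    d = cdist(static.coords, mobile.coords)
    pairs = []
    used_s: set[int] = set()
    used_m: set[int] = set()
    for idx in np.argsort(d, axis=None):
        i, j = np.unravel_index(idx, d.shape)
        ri, rj = int(static.res_numbers[i]), int(mobile.res_numbers[j])
        if d[i, j] > max_no:
            break
        if ri in used_s or rj in used_m:
            continue
        used_s.add(ri)
        used_m.add(rj)
        pairs.append((ri, rj, i, j))
        if len(pairs) == n_pairs:
            break

    def with_marker(model: StructureModel, res: int, resname: str,
                    atom: str, pos: np.ndarray) -> StructureModel:
        names = model.res_names.copy()
        names[model.res_numbers == res] = resname
        return StructureModel(
            np.append(model.chains, model.chains[0]),
            np.append(model.res_numbers, res),
            np.append(names, resname),
            np.append(model.atom_names, atom),
            np.append(model.elements, atom[0]),
            np.vstack([model.coords, pos]),
        )

    bridges = []
    for ri, rj, i, j in pairs:
        static = with_marker(static, ri, "ARG", "NH1", static.coords[i])
        mobile = with_marker(mobile, rj, "ASP", "OD1", mobile.coords[j])
        bridges.append((ri, rj))
    return static, mobile, bridges


def make_bipartite_truth(seed: int = 0, config: SimConfig | None = None) -> GroundTruth:
    """Build the default synthetic complex.

    A static receptor block (80 jittered lattice beads) carries two
    binding surfaces on opposite faces; each 36-bead ligand lobe has a
    contact layer molded into the hollows of its face, so the true pose
    is the unique tight, clash-free nesting.  The two lobes are tethered
    by a 36-residue flexible linker.  Two contact-bead pairs per strong
    site carry ARG/ASP marker atoms forming inter-molecular salt
    bridges.  Per-residue maximum shift perturbations are drawn once
    from ranges typical of interface CSPs (0.15-0.45 ppm 1H, 0.5-3 ppm
    15N, random sign); broadening factors are drawn log-uniformly so
    interface peaks lose 10-fold to several-hundred-fold intensity, up
    to disappearance, as seen in intermediate/slow exchange.
    """
    config = config or SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    static = make_lobe(80, 101, chain="A", shape=(5, 4, 4), jitter=0.6, rng=rng)
    mobile_a = _make_molded_mobile(static, 1001, "B", rng, direction=+1)
    mobile_b = _make_molded_mobile(static, 2001, "C", rng, direction=-1)
    static, mobile_a, bridges = _add_salt_bridge_markers(static, mobile_a)
    ia_s, ia_m = _contact_residues(static, mobile_a)
    ib_s, ib_m = _contact_residues(static, mobile_b)
    dmax_h: dict[int, float] = {}
    dmax_n: dict[int, float] = {}
    beta: dict[int, float] = {}
    for res in ia_s + ia_m + ib_s + ib_m:
        dmax_h[res] = float(rng.uniform(0.15, 0.45) * rng.choice([-1, 1]))
        dmax_n[res] = float(rng.uniform(0.5, 3.0) * rng.choice([-1, 1]))
        beta[res] = float(np.exp(rng.uniform(math.log(30.0), math.log(600.0))))
    tensors = {
        "pair_a": AlignmentTensor.from_da_r(-13.9, 0.56),
        "pair_b": AlignmentTensor.from_da_r(11.2, 0.35),
    }
    linker = LinkerSpec("mobile_a", 1036, "mobile_b", 2001, 36)
    return GroundTruth(
        static, mobile_a, mobile_b,
        ia_s, ia_m, ib_s, ib_m,
        dmax_h=dmax_h, dmax_n=dmax_n, broadening_beta=beta,
        tensors=tensors, linker=linker, seed=seed,
        salt_bridges=bridges,
    )


# ---------------------------------------------------------------------------
# Equilibrium

def fraction_bound(p_total_uM: float, l_total_uM: float, kd_uM: float) -> float:
    """Exact fraction of labeled protein bound for 1:1 binding.

    ``f = [(P + L + K_d) - sqrt((P + L + K_d)^2 - 4 P L)] / (2 P)``.
    ``kd_uM = inf`` is accepted and gives 0 (no binding).
    """
    if p_total_uM <= 0:
        raise ValueError("labeled protein concentration must be positive")
    if l_total_uM < 0 or kd_uM <= 0:
        raise ValueError("need L >= 0 and K_d > 0")
    if math.isinf(kd_uM) or l_total_uM == 0:
        return 0.0
    s = p_total_uM + l_total_uM + kd_uM
    disc = s * s - 4.0 * p_total_uM * l_total_uM
    return (s - math.sqrt(max(disc, 0.0))) / (2.0 * p_total_uM)


# ---------------------------------------------------------------------------
# Generators

_SITES = {"a": ("kd_a_uM", "interface_static_a", "interface_mobile_a"),
          "b": ("kd_b_uM", "interface_static_b", "interface_mobile_b")}


def _labeled_residues(truth: GroundTruth, labeled: str) -> np.ndarray:
    model = getattr(truth, labeled)
    return np.unique(model.res_numbers.astype(int))


def _interface_for(truth: GroundTruth, labeled: str, site: str) -> list[int]:
    kd_attr, s_attr, m_attr = _SITES[site]
    return getattr(truth, s_attr) if labeled == "static" else getattr(truth, m_attr)


def simulate_titration(
    truth: GroundTruth,
    config: SimConfig,
    mode: str,
    labeled: str = "static",
    site: str = "a",
    kd_uM: float | None = None,
    beta: float | None = None,
) -> TitrationSeries:
    """HSQC titration series with known ground truth.

    fast mode: interface peaks move by ``f_bound * dmax`` (population-
    weighted fast-exchange average) plus Gaussian shift noise.
    broadening mode: interface peaks lose intensity as
    ``I = I0 / (1 + beta * f_bound)`` plus intensity noise.  Non-
    interface residues see noise only.  Deterministic for a fixed
    config seed.
    """
    if mode not in ("fast", "broadening"):
        raise ValueError(f"unknown titration mode {mode!r}")
    site_kd = kd_uM if kd_uM is not None else getattr(truth, _SITES[site][0])
    interface = set(_interface_for(truth, labeled, site))
    residues = _labeled_residues(truth, labeled)
    rng = np.random.default_rng(config.seed)
    base_h = 7.5 + 1.5 * rng.random(len(residues))
    base_n = 110.0 + 20.0 * rng.random(len(residues))
    base_i = 1000.0 * (0.8 + 0.4 * rng.random(len(residues)))
    noise_sigma = max(config.intensity_noise_frac, 1e-6) * 1000.0
    points = []
    for conc in config.ligand_ladder_uM:
        f = fraction_bound(config.protein_uM, conc, site_kd)
        h = base_h.copy()
        n = base_n.copy()
        inten = base_i.copy()
        for k, res in enumerate(residues):
            if res in interface:
                if mode == "fast":
                    h[k] += f * truth.dmax_h.get(int(res), 0.0)
                    n[k] += f * truth.dmax_n.get(int(res), 0.0)
                else:
                    b = beta if beta is not None else truth.broadening_beta.get(int(res), 0.0)
                    inten[k] = base_i[k] / (1.0 + b * f)
        h += rng.normal(0, config.shift_noise_h_ppm, len(h)) if config.shift_noise_h_ppm else 0.0
        n += rng.normal(0, config.shift_noise_n_ppm, len(n)) if config.shift_noise_n_ppm else 0.0
        if config.intensity_noise_frac:
            inten += rng.normal(0, noise_sigma, len(inten))
        points.append(PeakList(residues.copy(), h, n, inten,
                               np.full(len(residues), noise_sigma),
                               ligand_uM=float(conc), protein_uM=config.protein_uM))
    return TitrationSeries(points)


def simulate_rdc(
    truth: GroundTruth,
    model: StructureModel,
    domain_pair: str,
    config: SimConfig,
    medium: str = "bicelle",
    residues=None,
) -> pd.DataFrame:
    """Observed RDCs = tensor back-calculation + Gaussian noise (Hz)."""
    if domain_pair not in truth.tensors:
        raise KeyError(f"no tensor defined for pair {domain_pair!r}")
    tensor = truth.tensors[domain_pair]
    calc = back_calc_rdc(tensor, model, residues=residues)
    # stable per-pair sub-seed (Python's str hash is salted per process)
    sub = sum(ord(c) for c in domain_pair) % 10000
    rng = np.random.default_rng(config.seed + sub)
    noise = rng.normal(0, config.rdc_noise_hz, len(calc)) if config.rdc_noise_hz else 0.0
    return pd.DataFrame({
        "residue": calc["residue"],
        "d_obs_hz": calc["d_calc_hz"] + noise,
        "error_hz": np.full(len(calc), max(config.rdc_noise_hz, 1e-9)),
        "medium": medium,
    })


def simulate_saxs(
    model: StructureModel,
    q: np.ndarray,
    config: SimConfig,
    n_replicas: int = 1,
    replica_scales: tuple = (1.0, 0.75, 0.5, 0.25),
) -> list[ScatteringCurve]:
    """Debye curve(s) with multiplicative Gaussian noise.

    With ``n_replicas > 1`` each replica is scaled (emulating a
    concentration series) before noise, for scale/merge testing.  The
    sigma column records the injected noise level.
    """
    ideal = debye_curve(model, q)
    rng = np.random.default_rng(config.seed)
    out = []
    for r in range(n_replicas):
        scale = replica_scales[r % len(replica_scales)]
        I0 = scale * ideal.intensity
        sigma = np.maximum(config.saxs_noise_frac * I0, 1e-12)
        noise = rng.normal(0, 1, len(I0)) * sigma if config.saxs_noise_frac else 0.0
        out.append(ScatteringCurve(ideal.q.copy(), I0 + noise, sigma,
                                   label=f"replica{r}"))
    return out


def simulate_binding(
    truth: GroundTruth,
    config: SimConfig,
    mode: str = "one-site",
    concentrations: np.ndarray | None = None,
    b_max: float = 1.0,
    ns_slope: float = 0.0,
    background: float = 0.0,
    c_eff_uM: float = 4.0e4,
    n_replicates: int = 3,
    assay: str = "plate",
) -> BindingCurve:
    """Saturable binding responses with nonspecific background and noise.

    one-site: the strong site alone.  two-site: an avid component at
    the enhanced apparent K_d plus a weak single-site component, which
    produces the curved Scatchard characteristic of tethered bivalent
    binding.
    """
    if concentrations is None:
        concentrations = np.array([0.5, 1, 2, 5, 10, 20, 50, 100, 200, 400], float)
    concentrations = np.asarray(concentrations, float)
    if len(concentrations) == 0:
        raise ValueError("empty concentration ladder")
    rng = np.random.default_rng(config.seed)
    x = np.tile(concentrations, n_replicates)
    rep = np.repeat(np.arange(n_replicates), len(concentrations))
    if mode == "one-site":
        y = one_site_total(x, truth.kd_a_uM, b_max, ns_slope, background)
    elif mode == "two-site":
        kd_app = avidity_apparent_kd(truth.kd_a_uM, truth.kd_b_uM, c_eff_uM)
        y = (0.5 * b_max * x / (kd_app + x)
             + 0.5 * b_max * x / (truth.kd_a_uM + x)
             + ns_slope * x + background)
    else:
        raise ValueError(f"unknown binding mode {mode!r}")
    if config.binding_noise_frac:
        # response-proportional noise with a small instrument floor
        span = max(float(np.max(np.abs(y))), 1e-12)
        sigma = config.binding_noise_frac * (np.abs(y) + 0.05 * span)
        y = y + rng.normal(0, 1, len(y)) * sigma
    return BindingCurve(x, y, rep, assay)
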