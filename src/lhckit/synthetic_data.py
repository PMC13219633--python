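"""Ground-truth fixture generator: helical bundles, antenna rings,
placed macrocycles and simulated maps.

The generator emulates the geometry the analyses assume — a tall "core"
helix bundle surrounded by rings ("belts") of shorter three-helix
antenna bundles, with flat chlorophyll-like macrocycles placed at
prescribed edge-to-edge distances on prescribed membrane sides — and
records machine-readable truth (per-helix axis arc lengths and residue
ranges, per-pair distances, the membrane frame, subfamily labels)
alongside every fixture.  Helices are ideal Cα spirals (radius 2.3 Å,
100°/residue) wound about a straight or circularly-arced axis; the true
height of a helix is the analytic arc length of its generating axis.

Randomness enters only through unconstrained placements and is governed
by a single integer seed; identical spec + seed give identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from lhckit.structure_io import AtomSite, MolecularModel, SubunitAnnotation
from lhckit.qscore import simulate_map

__all__ = [
    "HelixSpec", "BundleSpec", "MacrocyclePlacement", "SceneSpec",
    "make_helix", "make_bundle", "make_scene", "make_subfamily_analogs",
    "macrocycle_template", "write_truth",
]

CA_RADIUS = 2.3          # Å, Cα distance from the helix axis
TWIST_DEG = 100.0        # per-residue rotation
MIN_ARC_RADIUS = 10.0    # Å, tighter arcs are infeasible for a TM helix
CLASH_CUTOFF = 1.5       # Å, minimum inter-residue heavy-atom distance


@dataclass
class HelixSpec:
    length: int                 # residues
    rise: float = 1.5           # Å per residue along the axis
    tilt_deg: float = 0.0       # from the membrane normal
    arc_radius: float | None = None   # curved axis when set
    anchor: tuple[float, float] = (0.0, 0.0)  # midplane crossing, Å
    phase_deg: float = 0.0      # spiral phase
    tilt_azimuth_deg: float = 0.0

    def __post_init__(self):
        if self.length < 8:
            raise ValueError("helix length must be >= 8 residues")
        if not (1.0 <= self.rise <= 2.0):
            raise ValueError("rise must lie in [1.0, 2.0] Å/residue")
        if not (0.0 <= self.tilt_deg < 60.0):
            raise ValueError("tilt must lie in [0°, 60°)")
        if self.arc_radius is not None and self.arc_radius < MIN_ARC_RADIUS:
            raise ValueError(f"arc radius < {MIN_ARC_RADIUS} Å is infeasible")

    @property
    def true_height(self) -> float:
        """Analytic axis arc length covering residues 1..length."""
        return (self.length - 1) * self.rise


@dataclass
class BundleSpec:
    helices: list[HelixSpec]
    chain_id: str = "A"
    subfamily: str | None = None
    subunit_label: str = ""
    role: str = "core"


@dataclass
class MacrocyclePlacement:
    center: tuple[float, float, float]
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    kind: str = "chl_a"
    target_partner: int | None = None      # index of an earlier placement
    target_edge_to_edge: float | None = None


@dataclass
class SceneSpec:
    bundles: list[BundleSpec]
    macrocycles: list[MacrocyclePlacement] = field(default_factory=list)
    seed: int = 0


# ---------------------------------------------------------------------------
# helices

def _axis_frames(spec: HelixSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axis points and transported frame vectors for each residue."""
    n = spec.length
    L = spec.true_height
    s = -L / 2 + np.arange(n) * spec.rise     # arc-length parameter
    tilt = np.radians(spec.tilt_deg)
    az = np.radians(spec.tilt_azimuth_deg)
    # tilted direction and a perpendicular pair
    d = np.array([np.sin(tilt) * np.cos(az), np.sin(tilt) * np.sin(az),
                  np.cos(tilt)])
    e1 = np.array([np.cos(tilt) * np.cos(az), np.cos(tilt) * np.sin(az),
                   -np.sin(tilt)])
    e2 = np.cross(d, e1)
    anchor = np.array([spec.anchor[0], spec.anchor[1], 0.0])
    if spec.arc_radius is None:
        axis = anchor[None, :] + s[:, None] * d[None, :]
        t_hat = np.tile(d, (n, 1))
        n1 = np.tile(e1, (n, 1))
        n2 = np.tile(e2, (n, 1))
    else:
        R = spec.arc_radius
        theta = s / R
        # arc in the (d, e1) plane, tangent d at s = 0, passing the anchor
        center = anchor - R * e1
        axis = (center[None, :]
                + R * np.cos(theta)[:, None] * e1[None, :]
                + R * np.sin(theta)[:, None] * d[None, :])
        t_hat = (np.cos(theta)[:, None] * d[None, :]
                 - np.sin(theta)[:, None] * e1[None, :])
        n1 = (np.cos(theta)[:, None] * e1[None, :]
              + np.sin(theta)[:, None] * d[None, :])
        n2 = np.tile(e2, (n, 1))
    return axis, n1, n2


def make_helix(spec: HelixSpec, chain_id: str = "A", start_res: int = 1
               ) -> tuple[list[AtomSite], dict]:
    """Ideal α-helical Cα trace wound about the spec's axis.

    Returns the atoms and a truth record with the analytic height.
    """
    axis, n1, n2 = _axis_frames(spec)
    phases = np.radians(spec.phase_deg + TWIST_DEG * np.arange(spec.length))
    xyz = (axis + CA_RADIUS * (np.cos(phases)[:, None] * n1
                               + np.sin(phases)[:, None] * n2))
    atoms = [AtomSite(chain_id=chain_id, residue_name="ALA",
                      residue_seq=start_res + i, insertion_code=" ",
                      atom_name="CA", element="C", position=xyz[i])
             for i in range(spec.length)]
    truth = {"chain_id": chain_id, "start_res": start_res,
             "end_res": start_res + spec.length - 1,
             "height_A": spec.true_height,
             "rise_A": spec.rise, "tilt_deg": spec.tilt_deg,
             "arc_radius_A": spec.arc_radius,
             "axis_start": axis[0].tolist(), "axis_end": axis[-1].tolist()}
    return atoms, truth


RESIDUE_GAP = 5  # numbering gap between helices of one chain


def make_bundle(spec: BundleSpec) -> tuple[list[AtomSite], list[dict]]:
    atoms: list[AtomSite] = []
    truths: list[dict] = []
    next_res = 1
    for h in spec.helices:
        ha, ht = make_helix(h, chain_id=spec.chain_id, start_res=next_res)
        atoms.extend(ha)
        ht["subfamily"] = spec.subfamily
        ht["subunit_label"] = spec.subunit_label or spec.chain_id
        truths.append(ht)
        next_res = ht["end_res"] + 1 + RESIDUE_GAP
    return atoms, truths


# ---------------------------------------------------------------------------
# macrocycles

def macrocycle_template() -> tuple[list[str], np.ndarray]:
    """Idealized flat 25-atom tetrapyrrole: Mg + 4 N + 20 ring carbons.

    Geometry follows canonical chlorophyll macrocycle dimensions
    (N at ~2.0 Å from the metal, ring carbons at ~3.3 Å); atom names
    follow the chlorophyll component convention so the extraction
    rules treat synthetic and deposited pigments identically.
    """
    names = ["MG"]
    coords = [(0.0, 0.0)]
    for k, letter in enumerate("ABCD"):
        base = 45.0 + 90.0 * k
        names.append(f"N{letter}")
        coords.append((2.0, base))
        names.append(f"CH{letter}")
        coords.append((3.3, base - 45.0))
        for m, off in enumerate((-33.0, -11.0, 11.0, 33.0)):
            names.append(f"C{m + 1}{letter}")
            coords.append((3.3, base + off))
    xyz = np.array([[r * np.cos(np.radians(a)), r * np.sin(np.radians(a)), 0.0]
                    for r, a in coords])
    return names, xyz


def _ring_atoms(placement: MacrocyclePlacement, center: np.ndarray,
                chain_id: str, residue_seq: int) -> list[AtomSite]:
    names, flat = macrocycle_template()
    nrm = np.asarray(placement.normal, dtype=float)
    nrm = nrm / np.linalg.norm(nrm)
    ez = np.array([0.0, 0.0, 1.0])
    v = np.cross(ez, nrm)
    c = float(ez @ nrm)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1 + c)
    xyz = flat @ R.T + center
    resname = {"chl_a": "CLA", "chl_c": "KC2"}.get(placement.kind, "CLA")
    return [AtomSite(chain_id=chain_id, residue_name=resname,
                     residue_seq=residue_seq, insertion_code=" ",
                     atom_name=nm, element="MG" if nm == "MG" else "C",
                     position=p, is_hetero=True)
            for nm, p in zip(names, xyz)]


def _min_interring_distance(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial.distance import cdist
    return float(cdist(a, b).min())


def _solve_constrained_center(partner_xyz: np.ndarray,
                              placement: MacrocyclePlacement) -> np.ndarray:
    """Translate along the inter-ring axis until the edge-to-edge
    distance hits the target (bisection; monotone along the axis)."""
    target = placement.target_edge_to_edge
    c0 = np.asarray(placement.center, dtype=float)
    pc = partner_xyz.mean(axis=0)
    axis = c0 - pc
    if np.linalg.norm(axis) < 1e-9:
        axis = np.array([1.0, 0.0, 0.0])
    axis = axis / np.linalg.norm(axis)

    names, flat = macrocycle_template()

    def ring_at(t: float) -> np.ndarray:
        # orientation matches _ring_atoms for the placement's normal
        nrm = np.asarray(placement.normal, dtype=float)
        nrm = nrm / np.linalg.norm(nrm)
        ez = np.array([0.0, 0.0, 1.0])
        v = np.cross(ez, nrm)
        c = float(ez @ nrm)
        if np.linalg.norm(v) < 1e-12:
            R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]],
                           [-v[1], v[0], 0]])
            R = np.eye(3) + vx + vx @ vx / (1 + c)
        return flat @ R.T + (c0 + t * axis)

    def f(t: float) -> float:
        return _min_interring_distance(ring_at(t), partner_xyz) - target

    # bracket: coincident centres (edge distance 0) .. far apart
    t_lo = -float(np.linalg.norm(c0 - pc))
    t_hi = 60.0
    while f(t_hi) < 0 and t_hi < 1e4:
        t_hi *= 2
    if f(t_lo) * f(t_hi) > 0:
        raise ValueError("cannot satisfy edge-to-edge constraint by "
                         "translation along the inter-ring axis")
    for _ in range(80):
        t_mid = 0.5 * (t_lo + t_hi)
        if f(t_lo) * f(t_mid) <= 0:
            t_hi = t_mid
        else:
            t_lo = t_mid
    return c0 + 0.5 * (t_lo + t_hi) * axis


# ---------------------------------------------------------------------------
# scenes

def _check_clashes(atoms: Sequence[AtomSite]) -> None:
    xyz = np.array([a.position for a in atoms])
    rid = [(a.chain_id, a.residue_seq) for a in atoms]
    tree = cKDTree(xyz)
    for i, j in tree.query_pairs(r=CLASH_CUTOFF):
        if rid[i] != rid[j]:
            raise ValueError(
                f"steric clash below {CLASH_CUTOFF} Å between {rid[i]} "
                f"and {rid[j]}")


def make_scene(spec: SceneSpec, check_clashes: bool = True
               ) -> tuple[MolecularModel, dict, list[SubunitAnnotation]]:
    """Assemble bundles + macrocycles into a model with ground truth.

    Deterministic for a fixed seed.  Constrained macrocycle placements
    are solved by translation along the inter-ring axis to within
    1e-3 Å of the target edge-to-edge distance.  Returns the model, the
    truth record and a chain annotation table (core chains are labelled
    by their subunit_label; a stromal marker chain named PsaC-like is
    NOT added automatically — scenes carry the frame in the truth).
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[AtomSite] = []
    helix_truths: list[dict] = []
    annotations: list[SubunitAnnotation] = []
    for bundle in spec.bundles:
        ba, bt = make_bundle(bundle)
        atoms.extend(ba)
        helix_truths.extend(bt)
        annotations.append(SubunitAnnotation(
            chain_id=bundle.chain_id,
            subunit_label=bundle.subunit_label or bundle.chain_id,
            role=bundle.role,
            subfamily=bundle.subfamily if bundle.role != "core" else None,
        ))

    ring_atoms_by_index: list[list[AtomSite]] = []
    pair_truths: list[dict] = []
    mchain = "z"
    for i, placement in enumerate(spec.macrocycles):
        if placement.target_partner is not None:
            if not (0 <= placement.target_partner < i):
                raise ValueError("target_partner must reference an earlier "
                                 "placement")
            partner = ring_atoms_by_index[placement.target_partner]
            partner_xyz = np.array([a.position for a in partner])
            center = _solve_constrained_center(partner_xyz, placement)
        else:
            center = np.asarray(placement.center, dtype=float)
        ra = _ring_atoms(placement, center, mchain, i + 1)
        ring_atoms_by_index.append(ra)
        atoms.extend(ra)
        if placement.target_partner is not None:
            a_xyz = np.array([a.position for a in ra])
            partner_xyz = np.array(
                [a.position for a in ring_atoms_by_index[placement.target_partner]])
            pair_truths.append({
                "a": [mchain, placement.target_partner + 1],
                "b": [mchain, i + 1],
                "edge_to_edge_A": _min_interring_distance(a_xyz, partner_xyz),
                "target_A": placement.target_edge_to_edge,
            })
    # unconstrained randomness placeholder (jitter reserved for future
    # use keeps the seeded stream in the contract)
    _ = rng.random()

    if check_clashes and atoms:
        _check_clashes(atoms)

    model = MolecularModel(f"scene_seed{spec.seed}", atoms)
    truth = {
        "seed": spec.seed,
        "frame": {"normal": [0.0, 0.0, 1.0], "midplane_point": [0.0, 0.0, 0.0],
                  "stromal_sign": 1},
        "helices": helix_truths,
        "pairs": pair_truths,
        "subfamilies": {b.chain_id: b.subfamily for b in spec.bundles},
    }
    return model, truth, annotations


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# canned scenes

def core_belt_scene(core_height: float = 48.0, belt_height: float = 31.0,
                    n_belt: int = 6, belt_radius: float = 25.0,
                    rise: float = 1.5, seed: int = 0) -> SceneSpec:
    """A tall core bundle ringed by shorter belt bundles.

    Defaults mirror the architecture of a photosystem core (helix
    heights up to ~48 Å) surrounded by a first antenna belt (~31 Å),
    giving a core-to-belt height contrast of 17 Å.
    """
    def helix_for(height: float, anchor, chain, label, role, subfamily=None):
        # choose a residue count whose exact rise reproduces the height
        length = round(height / rise) + 1
        exact_rise = height / (length - 1)
        if not (1.0 <= exact_rise <= 2.0):
            length += 1 if exact_rise > 2.0 else -1
            exact_rise = height / (length - 1)
        return BundleSpec(
            helices=[HelixSpec(length=length, rise=exact_rise, anchor=anchor)],
            chain_id=chain, subunit_label=label, role=role,
            subfamily=subfamily)

    bundles = [helix_for(core_height, (0.0, 0.0), "A", "core", "core")]
    for k in range(n_belt):
        ang = 2 * np.pi * k / n_belt
        anchor = (belt_radius * np.cos(ang), belt_radius * np.sin(ang))
        bundles.append(helix_for(belt_height, anchor, chr(ord("B") + k),
                                 f"belt{k + 1}", "belt1", "Lhcf"))
    return SceneSpec(bundles=bundles, seed=seed)


def random_bundle_spec(rng: np.random.Generator, n_helices: int = 3,
                       height_range: tuple[float, float] = (24.0, 48.0),
                       max_tilt: float = 25.0,
                       min_arc_radius: float = 100.0,
                       chain_id: str = "A",
                       spacing: float = 12.0) -> BundleSpec:
    """Bundle with prescribed random heights/tilts/curvature — the truth
    the measurement pipeline must recover."""
    helices = []
    for i in range(n_helices):
        rise = 1.5
        height = rng.uniform(*height_range)
        length = int(round(height / rise)) + 1
        tilt = rng.uniform(0.0, max_tilt)
        curved = rng.random() < 0.5
        arc = rng.uniform(min_arc_radius, 4 * min_arc_radius) if curved else None
        ang = 2 * np.pi * i / n_helices
        anchor = (spacing * np.cos(ang), spacing * np.sin(ang))
        helices.append(HelixSpec(length=length, rise=rise, tilt_deg=tilt,
                                 arc_radius=arc, anchor=anchor,
                                 tilt_azimuth_deg=float(rng.uniform(0, 360)),
                                 phase_deg=float(rng.uniform(0, 360))))
    return BundleSpec(helices=helices, chain_id=chain_id)


def helix_field(n_helices: int, seed: int = 0,
                height_range: tuple[float, float] = (24.0, 48.0),
                spacing: float = 14.0) -> tuple[MolecularModel, dict]:
    """A planar field of vertical single-helix chains at random heights.

    Used to stress neighbor-edge computations at scale; helices sit on a
    jittered square grid so the scene is packed like a real membrane
    without clashes.  Returns the model and its truth record.
    """
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_helices)))
    atoms: list[AtomSite] = []
    truths = []
    k = 0
    for gy in range(side):
        for gx in range(side):
            if k >= n_helices:
                break
            height = float(rng.uniform(*height_range))
            length = int(round(height / 1.5)) + 1
            rise = height / (length - 1)
            anchor = (gx * spacing + float(rng.uniform(-2, 2)),
                      gy * spacing + float(rng.uniform(-2, 2)))
            cid = f"h{k:04d}"
            ha, ht = make_helix(HelixSpec(length=length, rise=rise,
                                          anchor=anchor,
                                          phase_deg=float(rng.uniform(0, 360))),
                                chain_id=cid)
            atoms.extend(ha)
            ht["subunit_label"] = cid
            truths.append(ht)
            k += 1
    model = MolecularModel(f"helix_field_{n_helices}", atoms)
    truth = {"seed": seed,
             "frame": {"normal": [0.0, 0.0, 1.0],
                       "midplane_point": [0.0, 0.0, 0.0], "stromal_sign": 1},
             "helices": truths}
    return model, truth


def chromophore_field(n_rings: int, seed: int = 0,
                      spacing: float = 12.0) -> MolecularModel:
    """A slab of tilted macrocycles on a jittered grid (no clashes)."""
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_rings)))
    placements = []
    for k in range(n_rings):
        gx, gy = k % side, k // side
        tilt = rng.uniform(0, 35)
        az = rng.uniform(0, 2 * np.pi)
        normal = (np.sin(np.radians(tilt)) * np.cos(az),
                  np.sin(np.radians(tilt)) * np.sin(az),
                  np.cos(np.radians(tilt)))
        placements.append(MacrocyclePlacement(
            center=(gx * spacing + rng.uniform(-1.5, 1.5),
                    gy * spacing + rng.uniform(-1.5, 1.5),
                    rng.uniform(-7.0, 7.0)),
            normal=normal,
            kind="chl_a" if rng.random() < 0.8 else "chl_c"))
    model, _, _ = make_scene(SceneSpec(bundles=[], macrocycles=placements,
                                       seed=seed))
    model.identifier = f"chromophore_field_{n_rings}"
    return model


# ---------------------------------------------------------------------------
# subfamily analogs

def make_subfamily_analogs(short_helixC_len: int = 10,
                           long_helixC_len: int = 18,
                           n_chlorophylls: int = 3,
                           resolutions: Sequence[float] = (5.0,),
                           voxel: float = 1.0,
                           ) -> dict:
    """Two LHC-like 3-helix bundles differing only in helix-C length.

    Antenna subfamilies differ most visibly in the length/curvature of
    helix C (e.g. a short straight helix C versus a longer one); the
    analogs share helices A/B and chlorophyll placements so that any
    cross-fit discrimination must come from helix C.  Simulated maps at
    the requested resolutions are returned per analog.
    """
    if long_helixC_len - short_helixC_len < 4:
        raise ValueError("helix-C lengths must differ by >= 4 residues")

    def build(c_len: int, chain: str) -> MolecularModel:
        short = c_len == short_helixC_len
        # the short-helix-C analog is straight (Lhcf-like); the long one
        # is tilted and curved (Lhcr/Lhcq-like), so the two differ in
        # helix-C geometry, not merely by a truncation
        helix_c = HelixSpec(length=c_len, anchor=(0.0, 9.0), phase_deg=240.0,
                            tilt_deg=0.0 if short else 12.0,
                            arc_radius=None if short else 60.0,
                            tilt_azimuth_deg=90.0)
        bundles = [BundleSpec(helices=[
            HelixSpec(length=24, anchor=(-5.0, 0.0)),
            HelixSpec(length=24, anchor=(5.0, 0.0), phase_deg=120.0),
            helix_c,
        ], chain_id=chain, subunit_label=f"analog_{chain}", role="belt1",
            subfamily="Lhcf" if short else "Lhcr")]
        placements = [MacrocyclePlacement(center=(-5.0 + 9.0 * k, -8.0, 4.0))
                      for k in range(n_chlorophylls)]
        model, _, _ = make_scene(SceneSpec(bundles=bundles,
                                           macrocycles=placements, seed=0))
        model.identifier = f"analog_{chain}"
        return model

    short_model = build(short_helixC_len, "S")
    long_model = build(long_helixC_len, "L")
    maps = {
        "short": {r: simulate_map(short_model, r, voxel=voxel)
                  for r in resolutions},
        "long": {r: simulate_map(long_model, r, voxel=voxel)
                 for r in resolutions},
    }
    return {"short": short_model, "long": long_model, "maps": maps}
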