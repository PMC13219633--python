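"""Chlorophyll extraction, distance networks and cross-structure comparison.

Distances between chlorophylls are the standard proxies for excitation
energy transfer (EET): the edge-to-edge distance is the minimum
heavy-atom distance between two tetrapyrrole macrocycles (phytol tail
excluded), and the Mg--Mg distance is the distance between central
metals.  Networks connect pairs below a cutoff (default 15 Å), split by
membrane side.  Cross-structure comparison superposes two models
rigidly (Kabsch on paired Cα) and matches chlorophylls greedily by
metal proximity; unmatched reference pigments are "lost", unmatched
query pigments "gained".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from lhckit._superpose import kabsch
from lhckit.membrane_geometry import MembraneFrame
from lhckit.structure_io import AtomSite, MolecularModel

__all__ = [
    "ChromophoreModel", "PairDistance", "EETNetwork", "GainLossReport",
    "Transform", "DEFAULT_CATALOG", "extract_chromophores", "edge_to_edge",
    "mg_mg", "build_network", "closest_pair", "superpose",
    "compare_chromophores",
]

# Chemical-component codes for the pigments of red-lineage antennae.
# Keys are CCD residue names; values are coarse kinds.  User catalogs
# may extend or override (the chain/residue <-> pigment-number mapping
# is deposition-specific and supplied as configuration).
DEFAULT_CATALOG: dict[str, str] = {
    "CLA": "chl_a",          # chlorophyll a
    "CHL": "chl_a",          # chlorophyll b code; treated as generic chl
    "KC1": "chl_c",          # chlorophyll c1
    "KC2": "chl_c",          # chlorophyll c2
    "BCR": "carotenoid",     # beta-carotene
    "A86": "carotenoid",     # fucoxanthin
    "FXN": "carotenoid",
    "DD6": "carotenoid",     # diadinoxanthin
    "LUT": "carotenoid",
    "XAT": "carotenoid",     # violaxanthin
}

CHL_KINDS = frozenset({"chl_a", "chl_c"})
METAL_NAMES = frozenset({"MG", "MG1"})
MIDPLANE_MARGIN = 2.0  # Å; pigments closer to the midplane stay unassigned


def _is_phytol_atom(name: str) -> bool:
    """Phytol-tail carbons are plain-numbered (C1..C20) in chlorophyll
    components; macrocycle/first-shell atoms carry lettered names."""
    if not name.startswith("C"):
        return False
    return name[1:].isdigit()


@dataclass
class ChromophoreModel:
    """One pigment: macrocycle heavy atoms, central metal, membrane side."""

    chain_id: str
    residue_seq: int
    residue_name: str
    kind: str                       # chl_a | chl_c | carotenoid | other
    atom_names: list[str]
    macrocycle_xyz: np.ndarray      # (m, 3) heavy atoms incl. metal
    metal_position: np.ndarray | None
    side: str = "unassigned"        # stromal | lumenal | unassigned

    def __post_init__(self):
        self.macrocycle_xyz = np.asarray(self.macrocycle_xyz, dtype=float)
        if len(self.macrocycle_xyz) == 0:
            raise ValueError("macrocycle atom set must be non-empty")
        if self.metal_position is not None:
            self.metal_position = np.asarray(self.metal_position, dtype=float)

    @property
    def chrom_id(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_seq)

    @property
    def centroid(self) -> np.ndarray:
        return self.macrocycle_xyz.mean(axis=0)

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(
            self.macrocycle_xyz - self.centroid, axis=1).max())

    def transformed(self, transform: "Transform") -> "ChromophoreModel":
        return ChromophoreModel(
            self.chain_id, self.residue_seq, self.residue_name, self.kind,
            list(self.atom_names), transform.apply(self.macrocycle_xyz),
            None if self.metal_position is None
            else transform.apply(self.metal_position), self.side)


@dataclass
class PairDistance:
    a: tuple[str, int]
    b: tuple[str, int]
    edge_to_edge: float
    mg_mg: float | None
    same_side: bool
    cross_subunit: bool = False


@dataclass
class EETNetwork:
    """Chlorophyll distance network: edges where edge-to-edge <= cutoff."""

    chromophores: list[ChromophoreModel]
    edges: list[PairDistance]
    cutoff: float
    strict: bool = False

    @property
    def sides(self) -> dict[str, list[tuple[str, int]]]:
        part: dict[str, list[tuple[str, int]]] = {}
        for c in self.chromophores:
            part.setdefault(c.side, []).append(c.chrom_id)
        return part


@dataclass
class GainLossReport:
    matched: list[tuple[tuple[str, int], tuple[str, int], float]]
    lost: list[tuple[str, int]]      # reference-only
    gained: list[tuple[str, int]]    # query-only
    match_cutoff: float


@dataclass
class Transform:
    """Rigid transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        x = np.asarray(xyz, dtype=float)
        return x @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self ∘ other (apply other first)."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply_to_model(self, model: MolecularModel) -> MolecularModel:
        return model.transformed(self.rotation, self.translation)


# ---------------------------------------------------------------------------
# extraction

def extract_chromophores(model: MolecularModel,
                         frame: MembraneFrame | None = None,
                         residue_catalog: dict[str, str] | None = None,
                         midplane_margin: float = MIDPLANE_MARGIN
                         ) -> list[ChromophoreModel]:
    """One ChromophoreModel per catalogued hetero residue.

    For chlorophyll kinds the macrocycle set is every heavy atom except
    the plain-numbered phytol-tail carbons; the central Mg is included.
    The membrane side is the sign of the metal position (or macrocycle
    centroid when the metal is absent) relative to the midplane, with a
    ±``midplane_margin`` Å dead zone left unassigned.  Waters, ions and
    uncatalogued hetero residues are skipped; uncatalogued residue names
    are reported as a warning.
    """
    catalog = DEFAULT_CATALOG if residue_catalog is None else residue_catalog
    chroms: list[ChromophoreModel] = []
    unknown: set[str] = set()
    for rid, resname, atoms in model.hetero_residues():
        if resname == "HOH" or len(atoms) == 1:  # waters / lone ions
            continue
        kind = catalog.get(resname)
        if kind is None:
            unknown.add(resname)
            continue
        if kind in CHL_KINDS:
            ring = [a for a in atoms if not _is_phytol_atom(a.atom_name)]
        else:
            ring = list(atoms)
        if not ring:
            continue
        metal = next((a.position for a in ring
                      if a.atom_name.upper() in METAL_NAMES
                      or a.element.upper() == "MG"), None)
        if kind in CHL_KINDS and metal is None:
            warnings.warn(f"chlorophyll {resname} {rid} lacks its Mg; "
                          f"side taken from macrocycle centroid")
        xyz = np.array([a.position for a in ring])
        c = ChromophoreModel(
            chain_id=rid[0], residue_seq=rid[1], residue_name=resname,
            kind=kind, atom_names=[a.atom_name for a in ring],
            macrocycle_xyz=xyz, metal_position=metal,
        )
        if frame is not None:
            anchor = metal if metal is not None else c.centroid
            h = frame.signed_height(anchor)
            if abs(h) <= midplane_margin:
                c.side = "unassigned"
            else:
                c.side = "stromal" if h > 0 else "lumenal"
        chroms.append(c)
    if unknown:
        warnings.warn(f"uncatalogued hetero residues skipped: "
                      f"{sorted(unknown)}")
    return chroms


# ---------------------------------------------------------------------------
# distances

def edge_to_edge(c1: ChromophoreModel, c2: ChromophoreModel) -> float:
    """Minimum heavy-atom distance between two macrocycle atom sets."""
    if c1.chrom_id == c2.chrom_id:
        raise ValueError("self-distance is undefined")
    return float(cdist(c1.macrocycle_xyz, c2.macrocycle_xyz).min())


def mg_mg(c1: ChromophoreModel, c2: ChromophoreModel) -> float:
    """Central-metal distance; both chromophores must have a metal."""
    if c1.metal_position is None or c2.metal_position is None:
        raise ValueError("Mg-Mg distance requires central metals on both "
                         "chromophores")
    return float(np.linalg.norm(c1.metal_position - c2.metal_position))


def _pair_distance(c1: ChromophoreModel, c2: ChromophoreModel) -> PairDistance:
    both_metal = c1.metal_position is not None and c2.metal_position is not None
    return PairDistance(
        a=c1.chrom_id, b=c2.chrom_id,
        edge_to_edge=edge_to_edge(c1, c2),
        mg_mg=mg_mg(c1, c2) if both_metal else None,
        same_side=(c1.side == c2.side and c1.side != "unassigned"),
        cross_subunit=(c1.chain_id != c2.chain_id),
    )


def build_network(chromophores: Sequence[ChromophoreModel],
                  cutoff: float = 15.0, side_filter: str | None = None,
                  strict: bool = False,
                  include_carotenoids: bool = False) -> EETNetwork:
    """EET candidate network: pairs with edge-to-edge <= cutoff.

    ``strict`` uses a strict inequality ("closer than").  Carotenoids
    are carried through extraction but excluded from the network by
    default; ``side_filter`` restricts to one membrane side.
    """
    sel = [c for c in chromophores
           if include_carotenoids or c.kind in CHL_KINDS]
    if side_filter is not None:
        sel = [c for c in sel if c.side == side_filter]
    if len(sel) < 2:
        return EETNetwork(chromophores=sel, edges=[], cutoff=cutoff,
                          strict=strict)
    centroids = np.array([c.centroid for c in sel])
    radii = np.array([c.radius for c in sel])
    tree = cKDTree(centroids)
    candidates = tree.query_pairs(r=cutoff + 2 * radii.max())
    edges = []
    for i, j in sorted(candidates):
        d = edge_to_edge(sel[i], sel[j])
        if (d < cutoff) if strict else (d <= cutoff):
            edges.append(_pair_distance(sel[i], sel[j]))
    return EETNetwork(chromophores=sel, edges=edges, cutoff=cutoff,
                      strict=strict)


def closest_pair(group_a: Sequence[ChromophoreModel],
                 group_b: Sequence[ChromophoreModel],
                 side: str | None = None,
                 exclude: Iterable[tuple[str, int]] = ()) -> PairDistance:
    """Minimal cross-group edge-to-edge pair under an optional side filter.

    Ties break deterministically by (chain, residue) order.
    """
    excl = set(exclude)
    ga = [c for c in group_a if c.chrom_id not in excl
          and (side is None or c.side == side)]
    gb = [c for c in group_b if c.chrom_id not in excl
          and (side is None or c.side == side)]
    if not ga or not gb:
        raise ValueError("a group is empty after exclusions/side filter")
    best = None
    best_key = None
    for ca in ga:
        for cb in gb:
            if ca.chrom_id == cb.chrom_id:
                continue
            d = edge_to_edge(ca, cb)
            key = (d, min(ca.chrom_id, cb.chrom_id),
                   max(ca.chrom_id, cb.chrom_id))
            if best_key is None or key < best_key:
                best_key = key
                best = _pair_distance(ca, cb)
    if best is None:
        raise ValueError("no valid cross-group pair")
    return best


# ---------------------------------------------------------------------------
# superposition and comparison

def _paired_ca(mobile: MolecularModel, reference: MolecularModel,
               chain_pairing: dict[str, str]
               ) -> tuple[np.ndarray, np.ndarray]:
    """Match Cα atoms by residue number per paired chain; fall back to
    the ungapped offset maximizing the match count."""
    P, Q = [], []
    for mc, rc in chain_pairing.items():
        ma = {a.residue_seq: a.position for a in mobile.ca_atoms(mc)}
        ra = {a.residue_seq: a.position for a in reference.ca_atoms(rc)}
        common = sorted(set(ma) & set(ra))
        if len(common) >= 20:
            P.extend(ma[s] for s in common)
            Q.extend(ra[s] for s in common)
            continue
        # ungapped best offset
        mseq = sorted(ma)
        rseq = sorted(ra)
        best_off, best_n = None, 0
        for off in range(min(rseq) - max(mseq), max(rseq) - min(mseq) + 1):
            n = len(set(s + off for s in mseq) & set(rseq))
            if n > best_n:
                best_n, best_off = n, off
        if best_off is not None and best_n >= 3:
            for s in mseq:
                if s + best_off in ra:
                    P.append(ma[s])
                    Q.append(ra[s + best_off])
    return np.array(P), np.array(Q)


def superpose(mobile: MolecularModel, reference: MolecularModel,
              chain_pairing: dict[str, str],
              atom_selection: str = "ca") -> tuple[Transform, float]:
    """Least-squares rigid superposition of paired chains (Kabsch).

    Pairing is sequence-independent by residue number, with an ungapped
    best-offset fallback; fewer than 20 matched Cα atoms is an error.
    """
    if atom_selection != "ca":
        raise ValueError("only Cα superposition is supported")
    P, Q = _paired_ca(mobile, reference, chain_pairing)
    if len(P) < 20:
        raise ValueError(f"only {len(P)} matched Cα atoms (need >= 20)")
    R, t, rmsd = kabsch(P, Q)
    return Transform(R, t), rmsd


def compare_chromophores(reference: Sequence[ChromophoreModel],
                         query: Sequence[ChromophoreModel],
                         match_cutoff: float = 5.0) -> GainLossReport:
    """Match chlorophylls between two superposed structures.

    Greedy nearest-metal matching in ascending-distance order under
    ``match_cutoff`` Å (chl <-> chl only, kind need not agree); each
    chromophore is matched at most once.  Unmatched reference pigments
    are reported lost, unmatched query pigments gained.
    """
    ref = [c for c in reference if c.kind in CHL_KINDS]
    qry = [c for c in query if c.kind in CHL_KINDS]
    if not ref or not qry:
        raise ValueError("empty chlorophyll region on one side of the "
                         "comparison")

    def anchor(c):
        return c.metal_position if c.metal_position is not None else c.centroid

    rpos = np.array([anchor(c) for c in ref])
    qpos = np.array([anchor(c) for c in qry])
    D = cdist(rpos, qpos)
    order = [(D[i, j], i, j) for i in range(len(ref)) for j in range(len(qry))
             if D[i, j] <= match_cutoff]
    order.sort(key=lambda t: (t[0], ref[t[1]].chrom_id, qry[t[2]].chrom_id))
    used_r: set[int] = set()
    used_q: set[int] = set()
    matched = []
    for d, i, j in order:
        if i in used_r or j in used_q:
            continue
        used_r.add(i)
        used_q.add(j)
        matched.append((ref[i].chrom_id, qry[j].chrom_id, float(d)))
    lost = [ref[i].chrom_id for i in range(len(ref)) if i not in used_r]
    gained = [qry[j].chrom_id for j in range(len(qry)) if j not in used_q]
    return GainLossReport(matched=matched, lost=lost, gained=gained,
                          match_cutoff=match_cutoff)
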