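"""Atomic models, density grids and subunit annotations.

Reading and writing goes through :mod:`gemmi` (mmCIF/PDB for models,
MRC2014/CCP4 for maps).  The in-memory containers here are deliberately
small: a flat, ordered list of heavy-atom records plus a chain index for
models, and an origin + voxel-size + array triple for maps.  Everything
downstream (helix geometry, chromophore networks, Q-scores) consumes
these containers only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomSite", "MolecularModel", "SubunitAnnotation", "DensityGrid",
    "read_structure", "write_structure", "read_map", "write_map",
    "load_annotation",
]

ANTENNA_ROLES = frozenset({"belt1", "belt2", "outer"})
ROLES = frozenset({"core"}) | ANTENNA_ROLES
SUBFAMILIES = frozenset({
    "Lhcr", "Lhcf", "Lhcq", "Lhcx", "Lhcz", "CgLhcr9-like", "RedCAP",
    "unknown",
})


@dataclass
class AtomSite:
    """One heavy-atom record.

    Coordinates are in Å.  ``is_hetero`` marks HETATM records (ligands,
    pigments, ions); waters are carried but excluded from analyses by
    the downstream modules.
    """

    chain_id: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    atom_name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError("element must be non-empty")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)


class MolecularModel:
    """Ordered heavy-atom collection with a chain index.

    Atom order is stable under round-trip through :func:`write_structure`
    / :func:`read_structure`.
    """

    def __init__(self, identifier: str, atoms: Sequence[AtomSite]):
        self.identifier = identifier
        self.atoms: list[AtomSite] = list(atoms)
        self._chain_index: dict[str, list[int]] = {}
        for i, a in enumerate(self.atoms):
            self._chain_index.setdefault(a.chain_id, []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        return list(self._chain_index)

    def chain_atoms(self, chain_id: str) -> list[AtomSite]:
        return [self.atoms[i] for i in self._chain_index[chain_id]]

    def ca_atoms(self, chain_id: str) -> list[AtomSite]:
        """Cα atoms of a chain in residue order (polymer only)."""
        cas = [a for a in self.chain_atoms(chain_id)
               if a.atom_name == "CA" and not a.is_hetero]
        cas.sort(key=lambda a: (a.residue_seq, a.insertion_code))
        return cas

    def coords(self, atoms: Iterable[AtomSite] | None = None) -> np.ndarray:
        atoms = self.atoms if atoms is None else list(atoms)
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.position for a in atoms])

    def hetero_residues(self) -> list[tuple[tuple[str, int, str], str, list[AtomSite]]]:
        """Group HETATM records by residue; order of first appearance."""
        groups: dict[tuple[str, int, str], list[AtomSite]] = {}
        names: dict[tuple[str, int, str], str] = {}
        for a in self.atoms:
            if a.is_hetero:
                groups.setdefault(a.residue_id, []).append(a)
                names.setdefault(a.residue_id, a.residue_name)
        return [(rid, names[rid], atoms) for rid, atoms in groups.items()]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MolecularModel":
        """Return a rigid-moved copy (x -> R x + t)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_atoms = []
        for a in self.atoms:
            b = AtomSite(a.chain_id, a.residue_name, a.residue_seq,
                         a.insertion_code, a.atom_name, a.element,
                         R @ a.position + t, a.occupancy, a.b_factor,
                         a.is_hetero)
            new_atoms.append(b)
        return MolecularModel(self.identifier, new_atoms)


@dataclass
class SubunitAnnotation:
    """Binding of a model chain to its subunit name, belt role and subfamily."""

    chain_id: str
    subunit_label: str
    role: str
    subfamily: str | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role {self.role!r} not one of {sorted(ROLES)}")
        if self.subfamily is not None:
            if self.role not in ANTENNA_ROLES:
                raise ValueError("subfamily may only be set for antenna roles")
            if self.subfamily not in SUBFAMILIES:
                raise ValueError(f"unknown subfamily {self.subfamily!r}")


@dataclass
class DensityGrid:
    """A density map on a regular grid.

    ``values[i, j, k]`` is the density at Cartesian position
    ``origin + (i, j, k) * voxel_size``; axes are canonical x, y, z.
    """

    origin: np.ndarray
    voxel_size: np.ndarray
    values: np.ndarray
    declared_resolution: float | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3-D array with positive dims")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Cartesian Å -> fractional voxel indices."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size

    def interpolate(self, xyz: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at Cartesian points (n, 3); 0 outside."""
        from scipy.ndimage import map_coordinates
        pts = np.atleast_2d(np.asarray(xyz, dtype=float))
        idx = (pts - self.origin) / self.voxel_size
        return map_coordinates(self.values, idx.T, order=1, mode="constant",
                               cval=0.0)


# ---------------------------------------------------------------------------
# model I/O

def _collapse_altlocs(raw: list[tuple[str, AtomSite, float]]) -> list[AtomSite]:
    """Keep the highest-occupancy conformer per (residue, atom name).

    Tie-break: first encountered.  Never increases atom count.
    """
    best: dict[tuple, int] = {}
    out: list[AtomSite | None] = []
    for altloc, atom, occ in raw:
        key = (*atom.residue_id, atom.residue_name, atom.atom_name)
        if key not in best:
            best[key] = len(out)
            out.append(atom)
        else:
            i = best[key]
            if occ > out[i].occupancy:
                out[i] = atom
    return [a for a in out if a is not None]


def read_structure(path, format: str = "auto",
                   use_label_ids: bool = False) -> MolecularModel:
    """Read an atomic model from mmCIF or PDB.

    Hydrogens are dropped, alternate locations collapsed to the
    highest-occupancy conformer, and chain identifiers follow the
    author-assigned naming unless ``use_label_ids`` is set (mmCIF
    label_asym_id).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {"auto": gemmi.CoorFormat.Detect,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "pdb": gemmi.CoorFormat.Pdb}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path.name}: {exc}") from exc
    st.remove_hydrogens()
    if len(st) == 0:
        raise ValueError(f"{path.name}: no models in file")
    model = st[0]
    raw: list[tuple[str, AtomSite, float]] = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            cid = res.subchain if use_label_ids and res.subchain else chain.name
            for atom in res:
                occ = float(np.clip(atom.occ, 0.0, 1.0))
                site = AtomSite(
                    chain_id=cid,
                    residue_name=res.name,
                    residue_seq=res.seqid.num,
                    insertion_code=(res.seqid.icode or " ").strip() or " ",
                    atom_name=atom.name,
                    element=atom.element.name or "X",
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=occ,
                    b_factor=atom.b_iso,
                    is_hetero=het,
                )
                raw.append((atom.altloc or "", site, occ))
    atoms = _collapse_altlocs(raw)
    if not atoms:
        raise ValueError(f"{path.name}: empty model (no heavy atoms)")
    return MolecularModel(path.stem, atoms)


def write_structure(model: MolecularModel, path, format: str = "auto") -> None:
    """Write a model as PDB or mmCIF (format inferred from suffix if auto)."""
    if len(model) == 0:
        raise ValueError("refusing to write an empty model")
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")

    st = gemmi.Structure()
    st.name = model.identifier
    st.cell = gemmi.UnitCell(1, 1, 1, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    for cid in model.chain_ids:
        chain = gemmi.Chain(cid)
        current = None
        res = None
        for a in model.chain_atoms(cid):
            rid = (a.residue_seq, a.insertion_code, a.residue_name)
            if rid != current:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_seq, a.insertion_code or " ")
                res.het_flag = "H" if a.is_hetero else "A"
                chain.add_residue(res)
                current = rid
                res = chain[-1]
            atom = gemmi.Atom()
            atom.name = a.atom_name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.position)
            atom.occ = a.occupancy
            atom.b_iso = a.b_factor
            res.add_atom(atom)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    try:
        if format == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# map I/O

def read_map(path) -> DensityGrid:
    """Read an MRC2014/CCP4 map; axis order normalized to x, y, z.

    The origin honors the MRC ORIGIN header words when set, else the
    NXSTART-style start indices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        cc = gemmi.read_ccp4_map(str(path))
        cc.setup(0.0, gemmi.MapSetup.ReorderOnly)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read MRC map {path.name}: {exc}") from exc
    values = np.array(cc.grid.array, dtype=np.float32)
    nx, ny, nz = values.shape
    cell = cc.grid.unit_cell
    for name, word in (("NX", 1), ("NY", 2), ("NZ", 3)):
        if cc.header_i32(word) <= 0:
            raise ValueError(f"corrupt MRC header: non-positive {name}")
    voxel = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    if np.any(voxel <= 0):
        raise ValueError("corrupt MRC header: non-positive cell")
    origin = np.array([cc.header_float(w) for w in (50, 51, 52)])
    if not np.any(origin):
        start = np.array([cc.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = start * voxel
    # MRC carries no resolution field; callers set declared_resolution
    return DensityGrid(origin=origin, voxel_size=voxel, values=values)


def write_map(grid: DensityGrid, path) -> None:
    """Write a DensityGrid as MRC2014 (canonical axis order, P1 cell)."""
    path = Path(path)
    nx, ny, nz = grid.dims
    cc = gemmi.Ccp4Map()
    cc.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values,
                                                   dtype=np.float32))
    cc.grid.unit_cell = gemmi.UnitCell(nx * grid.voxel_size[0],
                                       ny * grid.voxel_size[1],
                                       nz * grid.voxel_size[2], 90, 90, 90)
    cc.grid.spacegroup = gemmi.SpaceGroup("P1")
    cc.update_ccp4_header()
    for word, val in zip((50, 51, 52), grid.origin):
        cc.set_header_float(word, float(val))
    try:
        cc.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# annotations

def load_annotation(path, model: MolecularModel | None = None
                    ) -> list[SubunitAnnotation]:
    """Load a chain -> subunit annotation table (CSV or TSV, header row).

    Columns: chain_id, subunit_label, role, subfamily (subfamily may be
    empty).  Duplicate chain ids are an error.  If ``model`` is given,
    chains present in only one of table/model are reported as warnings.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    required = {"chain_id", "subunit_label", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if df["chain_id"].duplicated().any():
        dups = df.loc[df["chain_id"].duplicated(), "chain_id"].tolist()
        raise ValueError(f"duplicate chain_id in annotation: {dups}")
    anns = []
    for _, row in df.iterrows():
        fam = row.get("subfamily", "")
        anns.append(SubunitAnnotation(
            chain_id=row["chain_id"],
            subunit_label=row["subunit_label"],
            role=row["role"],
            subfamily=fam if fam else None,
        ))
    if model is not None:
        table_chains = {a.chain_id for a in anns}
        model_chains = set(model.chain_ids)
        only_table = table_chains - model_chains
        only_model = model_chains - table_chains
        if only_table:
            warnings.warn(f"annotation chains absent from model: "
                          f"{sorted(only_table)}")
        if only_model:
            warnings.warn(f"model chains without annotation: "
                          f"{sorted(only_model)}")
    return anns


def annotation_lookup(annotations: Sequence[SubunitAnnotation]
                      ) -> dict[str, SubunitAnnotation]:
    return {a.chain_id: a for a in annotations}
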