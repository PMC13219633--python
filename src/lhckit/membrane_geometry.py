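"""Membrane frame, transmembrane helix detection and height measurement.

The membrane is modelled as a planar slab with a normal vector, a
midplane point and a stromal sign; all sidedness (stromal vs lumenal)
and all height projections derive from this frame.  Helices are detected
purely from Cα geometry, so the pipeline has no dependency on an
external secondary-structure program and is deterministic.

Height semantics
----------------
A transmembrane helix height is the piecewise arc length of its axis
polyline split into ``k >= 3`` equal sub-segments (curvature-aware), and
the normal-projected span is reported alongside so either convention can
be compared across structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from lhckit._superpose import kabsch
from lhckit.structure_io import MolecularModel, SubunitAnnotation

__all__ = [
    "MembraneFrame", "HelixSegment", "TMHelixMeasure",
    "assign_helices", "estimate_frame", "filter_transmembrane",
    "measure_height", "aggregate_heights",
]

MIN_HELIX_RESIDUES = 8
CA_I_IP4_RANGE = (4.8, 6.6)   # Å, i -> i+4 Cα distance for helical windows
RISE_RANGE = (1.1, 1.9)       # Å per residue along the local axis
AXIS_WINDOW = 4               # sliding-window size for axis centroids
KINK_ANGLE_DEG = 40.0         # split helices at sharper axis bends


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane normal + midplane point + which side is stromal."""

    normal: np.ndarray
    midplane_point: np.ndarray
    stromal_sign: int = 1

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        nrm = np.linalg.norm(n)
        if nrm == 0:
            raise ValueError("normal must be non-zero")
        object.__setattr__(self, "normal", n / nrm)
        object.__setattr__(self, "midplane_point",
                           np.asarray(self.midplane_point, dtype=float))
        if self.stromal_sign not in (1, -1):
            raise ValueError("stromal_sign must be +1 or -1")

    def signed_height(self, xyz: np.ndarray) -> np.ndarray:
        """Signed distance from midplane; positive on the stromal side."""
        d = (np.atleast_2d(np.asarray(xyz, float)) - self.midplane_point
             ) @ self.normal
        out = d * self.stromal_sign
        return out if out.size > 1 else float(out[0])

    def in_plane_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic orthonormal basis (u, v) of the midplane."""
        n = self.normal
        e = np.zeros(3)
        e[int(np.argmin(np.abs(n)))] = 1.0
        u = np.cross(n, e)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v

    def project_in_plane(self, xyz: np.ndarray) -> np.ndarray:
        """2-D coordinates of points projected onto the midplane."""
        u, v = self.in_plane_basis()
        d = np.atleast_2d(np.asarray(xyz, float)) - self.midplane_point
        return np.column_stack([d @ u, d @ v])

    def to_dict(self) -> dict:
        return {"normal": self.normal.tolist(),
                "midplane_point": self.midplane_point.tolist(),
                "stromal_sign": self.stromal_sign}

    @classmethod
    def from_dict(cls, d: dict) -> "MembraneFrame":
        return cls(np.array(d["normal"]), np.array(d["midplane_point"]),
                   int(d["stromal_sign"]))


@dataclass
class HelixSegment:
    """One detected helix: residue range plus its axis polyline."""

    chain_id: str
    start_res: int
    end_res: int
    axis_polyline: np.ndarray   # (m, 3), m >= 2, termini extrapolated

    def __post_init__(self):
        self.axis_polyline = np.asarray(self.axis_polyline, dtype=float)
        if self.axis_polyline.ndim != 2 or len(self.axis_polyline) < 2:
            raise ValueError("axis polyline needs >= 2 points")
        if not np.all(np.isfinite(self.axis_polyline)):
            raise ValueError("axis polyline must be finite")
        if self.n_residues < MIN_HELIX_RESIDUES:
            raise ValueError("helix below minimum length")

    @property
    def n_residues(self) -> int:
        return self.end_res - self.start_res + 1

    @property
    def end_to_end(self) -> np.ndarray:
        return self.axis_polyline[-1] - self.axis_polyline[0]

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.axis_polyline[0] + self.axis_polyline[-1])


@dataclass
class TMHelixMeasure:
    """Measured transmembrane helix: arc-length height + projected span."""

    helix: HelixSegment
    subunit_label: str
    stromal_end: np.ndarray
    lumenal_end: np.ndarray
    height: float
    height_projected: float
    n_subsegments: int

    def __post_init__(self):
        if self.n_subsegments < 3:
            raise ValueError("at least three sub-segment measurements required")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.height < self.height_projected - 1e-6:
            raise ValueError("arc length cannot be below projected span")


# ---------------------------------------------------------------------------
# helix detection

def _helical_runs(ca_xyz: np.ndarray,
                  residue_seq: np.ndarray) -> list[tuple[int, int]]:
    """Runs of helical residues (index ranges, inclusive) from Cα geometry.

    A window is only considered when its five residues are consecutive
    in sequence, and runs are split at chain breaks (non-consecutive
    numbering), so adjacent helices of one chain never merge.
    """
    n = len(ca_xyz)
    if n < MIN_HELIX_RESIDUES:
        return []
    # axis points: centroid of AXIS_WINDOW consecutive Cα
    axis = np.array([ca_xyz[j:j + AXIS_WINDOW].mean(axis=0)
                     for j in range(n - AXIS_WINDOW + 1)])
    helical = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if residue_seq[i + 4] - residue_seq[i] != 4:
            continue
        d = np.linalg.norm(ca_xyz[i + 4] - ca_xyz[i])
        if not (CA_I_IP4_RANGE[0] <= d <= CA_I_IP4_RANGE[1]):
            continue
        rise = np.linalg.norm(axis[i + 1] - axis[i]) if i + 1 < len(axis) \
            else None
        if rise is not None and not (RISE_RANGE[0] <= rise <= RISE_RANGE[1]):
            continue
        helical[i:i + 5] = True
    breaks = np.zeros(n, dtype=bool)
    breaks[1:] = np.diff(residue_seq) != 1
    runs = []
    i = 0
    while i < n:
        if helical[i]:
            j = i
            while j + 1 < n and helical[j + 1] and not breaks[j + 1]:
                j += 1
            if j - i + 1 >= MIN_HELIX_RESIDUES:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _axis_polyline(ca_xyz: np.ndarray) -> np.ndarray:
    """Sliding-window axis with termini extrapolated to residues 1 and n.

    Window-4 Cα centroids retain a small residual spiral (the 3.6-residue
    period does not cancel exactly in four points); a second moving
    average over four centroids suppresses it to ~0.02 Å.  The smoothed
    point at position j is centred 3 residues inside the helix, so each
    terminus is extended by 3 local inter-point steps to cover the full
    residue range.
    """
    p = np.array([ca_xyz[j:j + AXIS_WINDOW].mean(axis=0)
                  for j in range(len(ca_xyz) - AXIS_WINDOW + 1)])
    if len(p) >= AXIS_WINDOW + 1:
        q = np.array([p[j:j + AXIS_WINDOW].mean(axis=0)
                      for j in range(len(p) - AXIS_WINDOW + 1)])
        inset = 3.0
    else:
        q, inset = p, 1.5
    if len(q) < 2:
        raise ValueError("helix too short for an axis polyline")
    head = q[0] - inset * (q[1] - q[0])
    tail = q[-1] + inset * (q[-1] - q[-2])
    return np.vstack([head, q, tail])


def _split_at_kinks(indices: tuple[int, int], ca_xyz: np.ndarray,
                    kink_angle: float) -> list[tuple[int, int]]:
    """Split a run at interior axis-direction changes > kink_angle (deg)."""
    a, b = indices
    seg = ca_xyz[a:b + 1]
    m = len(seg) - AXIS_WINDOW + 1
    if m < 9:  # need room on both sides of a candidate kink
        return [indices]
    p = np.array([seg[j:j + AXIS_WINDOW].mean(axis=0) for j in range(m)])
    cos_lim = np.cos(np.radians(kink_angle))
    # arm directions skip the centroids nearest the candidate kink:
    # those average atoms from both arms and would dilute the angle
    arm = 6 if m >= 13 else 4
    skip = 2 if arm == 6 else 1
    for j in range(arm, m - arm):
        d1 = p[j - skip] - p[j - arm]
        d2 = p[j + arm] - p[j + skip]
        c = d1 @ d2 / (np.linalg.norm(d1) * np.linalg.norm(d2))
        if c < cos_lim:
            cut = a + j + AXIS_WINDOW // 2
            left, right = (a, cut), (cut + 1, b)
            out = []
            for part in (left, right):
                if part[1] - part[0] + 1 >= MIN_HELIX_RESIDUES:
                    out.extend(_split_at_kinks(part, ca_xyz, kink_angle))
            return out or [indices]
    return [indices]


def assign_helices(model: MolecularModel,
                   kink_angle: float = KINK_ANGLE_DEG) -> list[HelixSegment]:
    """Detect helices chain-by-chain from Cα geometry.

    A residue is helical when it lies in an i -> i+4 window whose Cα
    distance is in [4.8, 6.6] Å and whose local axis rise is in
    [1.1, 1.9] Å; runs shorter than 8 residues are discarded and kinked
    helices (> 40° interior axis bend) are split.
    """
    segments: list[HelixSegment] = []
    for cid in model.chain_ids:
        cas = model.ca_atoms(cid)
        if len(cas) < MIN_HELIX_RESIDUES:
            if cas:
                warnings.warn(f"chain {cid}: fewer than {MIN_HELIX_RESIDUES} "
                              f"Cα atoms, no helices assigned")
            continue
        xyz = np.array([a.position for a in cas])
        seqs = np.array([a.residue_seq for a in cas])
        for (a, b) in _helical_runs(xyz, seqs):
            for (a2, b2) in _split_at_kinks((a, b), xyz, kink_angle):
                polyline = _axis_polyline(xyz[a2:b2 + 1])
                segments.append(HelixSegment(
                    chain_id=cid,
                    start_res=cas[a2].residue_seq,
                    end_res=cas[b2].residue_seq,
                    axis_polyline=polyline,
                ))
    return segments


# ---------------------------------------------------------------------------
# membrane frame

def estimate_frame(model: MolecularModel,
                   helices: Sequence[HelixSegment],
                   stromal_reference: str | np.ndarray | None = None,
                   annotation: Sequence[SubunitAnnotation] | None = None,
                   explicit_normal: np.ndarray | None = None) -> MembraneFrame:
    """Estimate the membrane frame from the helix bundle.

    The normal is the first principal axis of the helix end-to-end unit
    vectors; the midplane point is the centroid of helix axis midpoints.
    The stromal sign is set so that the stromal reference (a chain id,
    by default the chain annotated PsaC — a stromal-side subunit — or an
    explicit 3-vector point) lies on the positive side.  An explicit
    normal overrides the estimate verbatim after normalization.
    """
    if explicit_normal is not None:
        v = np.asarray(explicit_normal, dtype=float)
        if np.linalg.norm(v) == 0:
            raise ValueError("explicit normal must be non-zero")
        normal = v / np.linalg.norm(v)
        if len(helices) >= 1:
            mid = np.mean([h.midpoint for h in helices], axis=0)
        else:
            mid = model.coords().mean(axis=0)
    else:
        if len(helices) < 3:
            raise ValueError("need >= 3 transmembrane-scale helices to "
                             "estimate the membrane frame")
        U = np.array([h.end_to_end / np.linalg.norm(h.end_to_end)
                      for h in helices])
        M = U.T @ U
        w, V = np.linalg.eigh(M)
        if w[-2] > 0.6 * w[-1]:
            raise ValueError("degenerate helix directions; supply an "
                             "explicit membrane normal vector")
        normal = V[:, -1]
        mid = np.mean([h.midpoint for h in helices], axis=0)

    sign = 1
    ref_point = None
    if stromal_reference is None and annotation is not None:
        for ann in annotation:
            if ann.subunit_label.lower() == "psac":
                stromal_reference = ann.chain_id
                break
    if isinstance(stromal_reference, str):
        if stromal_reference in model.chain_ids:
            ref_point = model.coords(model.chain_atoms(stromal_reference)
                                     ).mean(axis=0)
        else:
            warnings.warn(f"stromal reference chain {stromal_reference!r} "
                          f"not in model; stromal_sign defaults to +1")
    elif stromal_reference is not None:
        ref_point = np.asarray(stromal_reference, dtype=float)
    if ref_point is not None:
        side = (ref_point - mid) @ normal
        sign = 1 if side >= 0 else -1
    return MembraneFrame(normal=normal, midplane_point=mid, stromal_sign=sign)


def filter_transmembrane(helices: Sequence[HelixSegment],
                         frame: MembraneFrame,
                         min_span: float = 15.0) -> list[HelixSegment]:
    """Keep helices spanning >= min_span along the normal and crossing
    the midplane (drops surface/amphipathic helices)."""
    kept = []
    for h in helices:
        proj = (h.axis_polyline - frame.midplane_point) @ frame.normal
        if proj.max() - proj.min() >= min_span and proj.min() < 0 < proj.max():
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# height measurement

def _polyline_point(polyline: np.ndarray, t: float) -> np.ndarray:
    """Point at fractional vertex parameter t in [0, m-1]."""
    i = int(np.floor(t))
    if i >= len(polyline) - 1:
        return polyline[-1]
    f = t - i
    return (1 - f) * polyline[i] + f * polyline[i + 1]


def measure_height(helix: HelixSegment, frame: MembraneFrame,
                   k: int = 3, subunit_label: str | None = None
                   ) -> TMHelixMeasure:
    """Measure one helix: k-chord arc length + normal-projected span.

    The axis polyline is split into ``k`` sub-segments of equal residue
    count and the height is the sum of the sub-segment chord lengths —
    a curvature-aware measurement requiring k >= 3.
    """
    if k < 3:
        raise ValueError("k must be >= 3 (minimum of three sub-segment "
                         "measurements)")
    P = helix.axis_polyline
    m = len(P)
    ts = np.linspace(0.0, m - 1.0, k + 1)
    pts = np.array([_polyline_point(P, t) for t in ts])
    height = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    height_projected = float(abs((P[-1] - P[0]) @ frame.normal))
    h0 = frame.signed_height(P[0])
    h1 = frame.signed_height(P[-1])
    if h1 >= h0:
        stromal_end, lumenal_end = P[-1], P[0]
    else:
        stromal_end, lumenal_end = P[0], P[-1]
    return TMHelixMeasure(
        helix=helix,
        subunit_label=subunit_label or helix.chain_id,
        stromal_end=np.array(stromal_end),
        lumenal_end=np.array(lumenal_end),
        height=height,
        height_projected=height_projected,
        n_subsegments=k,
    )


def measure_all(helices: Sequence[HelixSegment], frame: MembraneFrame,
                k: int = 3,
                annotation: Sequence[SubunitAnnotation] | None = None
                ) -> list[TMHelixMeasure]:
    """Convenience: measure every helix, labelling from the annotation."""
    lut = {a.chain_id: a.subunit_label for a in annotation} if annotation else {}
    return [measure_height(h, frame, k=k,
                           subunit_label=lut.get(h.chain_id, h.chain_id))
            for h in helices]


# ---------------------------------------------------------------------------
# aggregation

def _chain_rmsd(model: MolecularModel, cid_a: str, cid_b: str) -> float | None:
    """Cα superposition RMSD between two chains (residue-order pairing)."""
    xa = np.array([a.position for a in model.ca_atoms(cid_a)])
    xb = np.array([a.position for a in model.ca_atoms(cid_b)])
    n = min(len(xa), len(xb))
    if n < 8:
        return None
    # whole-subunit equivalence: require comparable chain lengths so a
    # short helix is never "pooled into" a sub-window of a longer one
    if n / max(len(xa), len(xb)) < 0.9:
        return None
    if len(xa) != len(xb):
        # ungapped best-offset pairing on the longer chain
        best = np.inf
        longer, shorter = (xa, xb) if len(xa) > len(xb) else (xb, xa)
        for off in range(len(longer) - n + 1):
            _, _, r = kabsch(shorter, longer[off:off + n])
            best = min(best, r)
        return float(best)
    _, _, r = kabsch(xa, xb)
    return float(r)


def aggregate_heights(measures: Sequence[TMHelixMeasure],
                      annotation: Sequence[SubunitAnnotation],
                      model: MolecularModel | None = None,
                      equivalence_rmsd: float = 0.55,
                      min_subfamily_n: int = 5
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subunit and per-subfamily mean heights.

    Chains whose Cα superposition RMSD is below ``equivalence_rmsd``
    (default 0.55 Å) are pooled and reported once.  Subfamily means
    pooled from fewer than ``min_subfamily_n`` representative chains are
    flagged as under-sampled.
    """
    lut = {a.chain_id: a for a in annotation}
    by_chain: dict[str, list[TMHelixMeasure]] = {}
    for mmeas in measures:
        by_chain.setdefault(mmeas.helix.chain_id, []).append(mmeas)

    chains = sorted(by_chain)
    # union-find pooling of structurally equivalent chains
    parent = {c: c for c in chains}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    if model is not None:
        for i, ca in enumerate(chains):
            for cb in chains[i + 1:]:
                r = _chain_rmsd(model, ca, cb)
                if r is not None and r < equivalence_rmsd:
                    parent[find(cb)] = find(ca)

    pools: dict[str, list[str]] = {}
    for c in chains:
        pools.setdefault(find(c), []).append(c)

    sub_rows = []
    for rep, members in sorted(pools.items()):
        ms = [m for c in members for m in by_chain[c]]
        ann = lut.get(rep)
        sub_rows.append({
            "subunit_label": ann.subunit_label if ann else rep,
            "chains": "+".join(members),
            "n_chains": len(members),
            "n_helices": len(ms),
            "mean_height_A": float(np.mean([m.height for m in ms])),
            "mean_height_projected_A": float(
                np.mean([m.height_projected for m in ms])),
            "subfamily": (ann.subfamily if ann else None) or "",
            "role": ann.role if ann else "",
        })
    subunit_df = pd.DataFrame(sub_rows)

    fam_rows = []
    by_family: dict[str, list[str]] = {}
    for c in chains:
        ann = lut.get(c)
        if ann is not None and ann.subfamily:
            by_family.setdefault(ann.subfamily, []).append(c)
    for fam, members in sorted(by_family.items()):
        ms = [m for c in members for m in by_chain[c]]
        fam_rows.append({
            "subfamily": fam,
            "n_representatives": len(members),
            "n_helices": len(ms),
            "mean_height_A": float(np.mean([m.height for m in ms])),
            "under_sampled": len(members) < min_subfamily_n,
        })
    subfamily_df = pd.DataFrame(fam_rows)
    return subunit_df, subfamily_df


def heights_table(measures: Sequence[TMHelixMeasure],
                  structure_id: str = "",
                  annotation: Sequence[SubunitAnnotation] | None = None
                  ) -> pd.DataFrame:
    """Per-helix heights as the exported CSV table."""
    columns = ["structure_id", "chain_id", "subunit_label", "subfamily",
               "helix_index", "residue_start", "residue_end", "height_A",
               "height_projected_A", "stromal_x", "stromal_y", "stromal_z"]
    lut = {a.chain_id: a for a in annotation} if annotation else {}
    rows = []
    for i, m in enumerate(measures):
        ann = lut.get(m.helix.chain_id)
        rows.append({
            "structure_id": structure_id,
            "chain_id": m.helix.chain_id,
            "subunit_label": m.subunit_label,
            "subfamily": (ann.subfamily if ann else None) or "",
            "helix_index": i,
            "residue_start": m.helix.start_res,
            "residue_end": m.helix.end_res,
            "height_A": m.height,
            "height_projected_A": m.height_projected,
            "stromal_x": m.stromal_end[0],
            "stromal_y": m.stromal_end[1],
            "stromal_z": m.stromal_end[2],
        })
    return pd.DataFrame(rows, columns=columns)
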