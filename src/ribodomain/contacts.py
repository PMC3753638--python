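"""Geometric detection and classification of RNA molecular interactions.

Detects, from raw 3D coordinates:

* base pairs, classified by Leontis–Westhof edge (Watson–Crick / Hoogsteen /
  Sugar) on each side and glycosidic-bond orientation (cis / trans);
* base stacking (centroid distance, plane-normal angle, vertical separation,
  projected ring overlap);
* base–phosphate and base–sugar hydrogen-bond contacts;
* RNA–Mg²⁺–RNA bridges (first coordination shell, strict ``< 2.6 Å``).

All thresholds live in :class:`DetectionParams` and are recorded verbatim in
the resulting :class:`ContactSet`, since every downstream count is
threshold-sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .model import NucleotideRecord, StructureModel

logger = logging.getLogger(__name__)

WATSON_CRICK = "WatsonCrick"
HOOGSTEEN = "Hoogsteen"
SUGAR = "SugarEdge"

_EDGE_LETTER = {WATSON_CRICK: "W", HOOGSTEEN: "H", SUGAR: "S"}

#: ring atoms (outer boundary, in connectivity order) per parent base
RING_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: polar base atoms considered as hydrogen-bond donors/acceptors in pairing
POLAR_BASE_ATOMS = {
    "A": ("N1", "N3", "N6", "N7"),
    "G": ("N1", "N2", "N3", "O6", "N7"),
    "C": ("N3", "N4", "O2"),
    "U": ("N3", "O2", "O4"),
}

#: atom sets defining each Leontis–Westhof edge, per parent base
EDGE_ATOMS = {
    "A": {WATSON_CRICK: {"N1", "C2", "N6"},
          HOOGSTEEN: {"N7", "C8", "N6"},
          SUGAR: {"N3", "O2'"}},
    "G": {WATSON_CRICK: {"N1", "C2", "O6"},
          HOOGSTEEN: {"N7", "C8", "O6"},
          SUGAR: {"N3", "N2", "O2'"}},
    "C": {WATSON_CRICK: {"N3", "N4", "O2"},
          HOOGSTEEN: {"N4", "C5", "C6"},
          SUGAR: {"O2", "O2'"}},
    "U": {WATSON_CRICK: {"N3", "O4", "O2"},
          HOOGSTEEN: {"O4", "C5", "C6"},
          SUGAR: {"O2", "O2'"}},
}

_CANONICAL_IDENTITIES = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                         ("G", "U"), ("U", "G")}

#: exocyclic heavy atoms included in the stacking footprint
EXOCYCLIC_ATOMS = {
    "A": ("N6",), "G": ("O6", "N2"), "C": ("N4", "O2"), "U": ("O4", "O2"),
}

PHOSPHATE_OXYGENS = ("OP1", "OP2", "O5'", "O3'")
SUGAR_OXYGENS = ("O2'", "O4'")


@dataclass(frozen=True)
class DetectionParams:
    """All geometric thresholds, in Å and degrees."""

    hbond_max: float = 3.5          # donor-acceptor distance ceiling
    min_hbonds: int = 2             # contacts required to call a pair
    plane_angle_max: float = 65.0   # inter-base-plane angle ceiling
    plane_sep_max: float = 2.0      # mean out-of-plane offset of contact atoms
    stack_centroid_max: float = 5.5
    stack_normal_max: float = 30.0
    stack_sep_min: float = 2.0
    stack_sep_max: float = 4.5
    stack_overlap_min: float = 0.0  # strict inequality
    stack_buffer: float = 0.5       # π-cloud extent beyond atom centers
    bp_cutoff: float = 3.5          # base-phosphate
    bs_cutoff: float = 3.5          # base-sugar
    mg_first_shell: float = 2.6     # strict inequality


@dataclass(frozen=True)
class BasePair:
    nt_i: tuple
    nt_j: tuple
    base_i: str
    base_j: str
    edge_i: str
    edge_j: str
    orientation: str          # "cis" | "trans"
    canonical: bool
    hbond_count: int
    hbond_mean_dist: float

    @property
    def lw_class(self) -> str:
        """FR3D-style class string, e.g. 'cWW' or 'tHS'."""
        return (("c" if self.orientation == "cis" else "t")
                + _EDGE_LETTER[self.edge_i] + _EDGE_LETTER[self.edge_j])

    @property
    def key(self) -> tuple:
        return (self.nt_i, self.nt_j)


@dataclass(frozen=True)
class StackingContact:
    nt_i: tuple
    nt_j: tuple
    centroid_dist: float
    normal_angle: float
    vertical_sep: float
    overlap_area: float

    @property
    def key(self) -> tuple:
        return (self.nt_i, self.nt_j)


@dataclass(frozen=True)
class AtomContact:
    """A base-to-backbone hydrogen-bond contact (base-phosphate or base-sugar)."""

    donor: tuple              # residue providing the base atom
    acceptor: tuple           # residue providing the backbone atom
    donor_atom: str
    acceptor_atom: str
    distance: float

    @property
    def key(self) -> tuple:
        return tuple(sorted((self.donor, self.acceptor)))


@dataclass(frozen=True)
class MgBridge:
    ion_id: str
    partners: tuple           # >= 2 residue refs, sorted
    partner_distances: tuple


@dataclass
class ContactSet:
    base_pairs: list = field(default_factory=list)
    stacks: list = field(default_factory=list)
    base_phosphate: list = field(default_factory=list)
    base_sugar: list = field(default_factory=list)
    mg_bridges: list = field(default_factory=list)
    params: DetectionParams = field(default_factory=DetectionParams)

    def params_dict(self) -> dict:
        return asdict(self.params)


# ---------------------------------------------------------------------------
# per-residue geometry


@dataclass
class _BaseFrame:
    ref: tuple
    base: str
    chain: str
    number: int
    ring: np.ndarray          # ring atom coords, connectivity order
    base_heavy: np.ndarray    # ring + exocyclic heavy atoms (stacking footprint)
    centroid: np.ndarray
    normal: np.ndarray        # unit
    c1: Optional[np.ndarray]
    glyco: Optional[np.ndarray]   # unit C1' -> N9/N1
    polar: dict               # atom name -> coord (base polar atoms + O2')


def _base_frame(nt: NucleotideRecord) -> Optional[_BaseFrame]:
    base = nt.base_type
    if base not in RING_ATOMS:
        return None
    ring = []
    for name in RING_ATOMS[base]:
        c = nt.coord(name)
        if c is None:
            logger.warning("residue %s missing ring atom %s; skipped", nt.ref, name)
            return None
        ring.append(c)
    ring = np.array(ring)
    centroid = ring.mean(axis=0)
    # plane normal by SVD of the centered ring
    _, _, vt = np.linalg.svd(ring - centroid)
    normal = vt[2]
    heavy = list(ring)
    for name in EXOCYCLIC_ATOMS[base]:
        c = nt.coord(name)
        if c is not None:
            heavy.append(c)
    heavy = np.array(heavy)
    c1 = nt.coord("C1'")
    ngly = nt.coord("N9" if base in ("A", "G") else "N1")
    glyco = None
    if c1 is not None and ngly is not None:
        g = ngly - c1
        glyco = g / np.linalg.norm(g)
    polar = {}
    for name in POLAR_BASE_ATOMS[base] + ("O2'",):
        c = nt.coord(name)
        if c is not None:
            polar[name] = c
    return _BaseFrame(nt.ref, base, nt.chain_id, nt.author_number,
                      ring, heavy, centroid, normal, c1, glyco, polar)


def _frames(model: StructureModel) -> list[_BaseFrame]:
    out = []
    for nt in sorted(model.nucleotides, key=lambda r: (r.chain_id, r.author_number)):
        fr = _base_frame(nt)
        if fr is not None:
            out.append(fr)
    return out


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    cosa = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# edge / orientation classification


class ClassificationError(ValueError):
    pass


def classify_edge(base: str, contact_atoms, distances=None) -> str:
    """Leontis–Westhof edge for a set of contacting atoms of one base.

    Plurality vote over the per-edge atom tables; ties broken by the smaller
    mean contact distance (when given), then by the fixed edge order
    WC > Hoogsteen > Sugar.
    """
    contact_atoms = list(contact_atoms)
    if not contact_atoms:
        raise ClassificationError("no contact atoms to classify")
    if base not in EDGE_ATOMS:
        raise ClassificationError(f"unknown base type {base!r}")
    scores = {}
    for edge in (WATSON_CRICK, HOOGSTEEN, SUGAR):
        members = [i for i, a in enumerate(contact_atoms)
                   if a in EDGE_ATOMS[base][edge]]
        if not members:
            continue
        mean_d = (np.mean([distances[i] for i in members])
                  if distances is not None else 0.0)
        scores[edge] = (len(members), -mean_d)
    if not scores:
        raise ClassificationError(
            f"atoms {contact_atoms} belong to no edge of base {base}")
    order = {WATSON_CRICK: 0, HOOGSTEEN: 1, SUGAR: 2}
    return max(scores, key=lambda e: (scores[e][0], scores[e][1], -order[e]))


def _cis_trans(fr_i: _BaseFrame, fr_j: _BaseFrame) -> str:
    """cis if the two glycosidic bonds fall on the same side of the C1'–C1' axis."""
    if fr_i.glyco is None or fr_j.glyco is None or fr_i.c1 is None or fr_j.c1 is None:
        return "cis"   # degenerate input; WC-like default
    axis = fr_j.c1 - fr_i.c1
    axis = axis / np.linalg.norm(axis)
    p_i = fr_i.glyco - np.dot(fr_i.glyco, axis) * axis
    p_j = fr_j.glyco - np.dot(fr_j.glyco, axis) * axis
    return "cis" if float(np.dot(p_i, p_j)) >= 0.0 else "trans"


# ---------------------------------------------------------------------------
# detectors


def detect_base_pairs(model: StructureModel,
                      params: DetectionParams = DetectionParams()) -> list[BasePair]:
    """Detect base pairs by geometric criteria.

    A pair requires >= ``min_hbonds`` polar-atom contacts within
    ``hbond_max``, near-coplanar base planes (angle <= ``plane_angle_max``)
    and contact atoms lying close to both base planes
    (<= ``plane_sep_max`` mean offset); the last criterion separates edge-on
    pairing from stacking.  A nucleotide may participate in several pairs
    (base triples).
    """
    frames = _frames(model)
    if not frames:
        return []
    atom_coords, atom_owner, atom_name = [], [], []
    for fi, fr in enumerate(frames):
        for name, c in fr.polar.items():
            atom_coords.append(c)
            atom_owner.append(fi)
            atom_name.append(name)
    atom_coords = np.array(atom_coords)
    tree = cKDTree(atom_coords)
    contacts: dict[tuple, list] = {}
    for a, b in tree.query_pairs(params.hbond_max):
        oi, oj = atom_owner[a], atom_owner[b]
        if oi == oj:
            continue
        if oi > oj:
            oi, oj, a, b = oj, oi, b, a
        d = float(np.linalg.norm(atom_coords[a] - atom_coords[b]))
        contacts.setdefault((oi, oj), []).append((atom_name[a], atom_name[b], d))

    pairs: list[BasePair] = []
    for (oi, oj), hits in sorted(contacts.items()):
        # O2'-O2' contacts alone are backbone geometry, not pairing
        base_hits = [h for h in hits if not (h[0] == "O2'" and h[1] == "O2'")]
        if len(base_hits) < params.min_hbonds:
            continue
        fr_i, fr_j = frames[oi], frames[oj]
        if _plane_angle(fr_i.normal, fr_j.normal) > params.plane_angle_max:
            continue
        pts_j = np.array([fr_j.polar[h[1]] for h in base_hits])
        pts_i = np.array([fr_i.polar[h[0]] for h in base_hits])
        sep_ij = np.mean(np.abs((pts_j - fr_i.centroid) @ fr_i.normal))
        sep_ji = np.mean(np.abs((pts_i - fr_j.centroid) @ fr_j.normal))
        if sep_ij > params.plane_sep_max or sep_ji > params.plane_sep_max:
            continue
        dists = [h[2] for h in base_hits]
        try:
            edge_i = classify_edge(fr_i.base, [h[0] for h in base_hits], dists)
            edge_j = classify_edge(fr_j.base, [h[1] for h in base_hits], dists)
        except ClassificationError:
            continue
        orientation = _cis_trans(fr_i, fr_j)
        canonical = (orientation == "cis"
                     and edge_i == WATSON_CRICK and edge_j == WATSON_CRICK
                     and (fr_i.base, fr_j.base) in _CANONICAL_IDENTITIES)
        pairs.append(BasePair(
            nt_i=fr_i.ref, nt_j=fr_j.ref, base_i=fr_i.base, base_j=fr_j.base,
            edge_i=edge_i, edge_j=edge_j, orientation=orientation,
            canonical=canonical, hbond_count=len(base_hits),
            hbond_mean_dist=float(np.mean(dists)),
        ))
    return pairs


def _footprint(coords_2d: np.ndarray, buffer: float) -> Polygon:
    """Stacking footprint: buffered convex hull of the projected base atoms."""
    from shapely.geometry import MultiPoint

    return MultiPoint(coords_2d.tolist()).convex_hull.buffer(buffer)


def detect_stacking(model: StructureModel,
                    params: DetectionParams = DetectionParams()) -> list[StackingContact]:
    """Detect base-stacking contacts (parallel, vertically offset, overlapping rings)."""
    frames = _frames(model)
    if len(frames) < 2:
        return []
    centroids = np.array([fr.centroid for fr in frames])
    tree = cKDTree(centroids)
    out: list[StackingContact] = []
    for oi, oj in sorted(tree.query_pairs(params.stack_centroid_max)):
        fr_i, fr_j = frames[oi], frames[oj]
        angle = _plane_angle(fr_i.normal, fr_j.normal)
        if angle > params.stack_normal_max:
            continue
        dvec = fr_j.centroid - fr_i.centroid
        sep = 0.5 * (abs(float(np.dot(dvec, fr_i.normal)))
                     + abs(float(np.dot(dvec, fr_j.normal))))
        if not (params.stack_sep_min <= sep <= params.stack_sep_max):
            continue
        # project both rings onto the plane of base i
        n = fr_i.normal
        basis_x = fr_i.ring[0] - fr_i.centroid
        basis_x = basis_x - np.dot(basis_x, n) * n
        basis_x /= np.linalg.norm(basis_x)
        basis_y = np.cross(n, basis_x)

        def proj(pts):
            rel = pts - fr_i.centroid
            return np.stack([rel @ basis_x, rel @ basis_y], axis=1)

        poly_i = _footprint(proj(fr_i.base_heavy), params.stack_buffer)
        poly_j = _footprint(proj(fr_j.base_heavy), params.stack_buffer)
        overlap = float(poly_i.intersection(poly_j).area)
        if overlap <= params.stack_overlap_min:
            continue
        out.append(StackingContact(
            nt_i=fr_i.ref, nt_j=fr_j.ref, centroid_dist=float(np.linalg.norm(dvec)),
            normal_angle=angle, vertical_sep=sep, overlap_area=overlap,
        ))
    return out


def _detect_base_to_backbone(model: StructureModel, backbone_atoms, cutoff: float):
    frames = {fr.ref: fr for fr in _frames(model)}
    donors, donor_info = [], []
    for nt in model.nucleotides:
        fr = frames.get(nt.ref)
        if fr is None:
            continue
        for name in POLAR_BASE_ATOMS[fr.base]:
            c = nt.coord(name)
            if c is not None:
                donors.append(c)
                donor_info.append((nt.ref, name))
    acceptors, acceptor_info = [], []
    for nt in model.nucleotides:
        for name in backbone_atoms:
            c = nt.coord(name)
            if c is not None:
                acceptors.append(c)
                acceptor_info.append((nt.ref, name))
    if not donors or not acceptors:
        return []
    tree = cKDTree(np.array(acceptors))
    best: dict[tuple, AtomContact] = {}
    for di, dcoord in enumerate(donors):
        for ai in tree.query_ball_point(dcoord, cutoff):
            dref, dname = donor_info[di]
            aref, aname = acceptor_info[ai]
            if dref == aref:
                continue
            d = float(np.linalg.norm(dcoord - np.array(acceptors[ai])))
            key = tuple(sorted((dref, aref)))
            if key not in best or d < best[key].distance:
                best[key] = AtomContact(dref, aref, dname, aname, d)
    return [best[k] for k in sorted(best)]


def detect_base_phosphate(model: StructureModel,
                          params: DetectionParams = DetectionParams()) -> list[AtomContact]:
    """Base polar atom to phosphate oxygen of a *different* residue, one contact
    (the closest) per residue pair."""
    return _detect_base_to_backbone(model, PHOSPHATE_OXYGENS, params.bp_cutoff)


def detect_base_sugar(model: StructureModel,
                      params: DetectionParams = DetectionParams()) -> list[AtomContact]:
    """Base polar atom to ribose O2'/O4' of a different residue."""
    return _detect_base_to_backbone(model, SUGAR_OXYGENS, params.bs_cutoff)


def detect_mg_bridges(model: StructureModel,
                      first_shell_cutoff: float = 2.6) -> list[MgBridge]:
    """Mg²⁺ ions whose first shell (strict ``< cutoff``) holds >= 2 RNA residues."""
    mg = [ion for ion in model.ions if ion.element.upper() == "MG"]
    if not mg or not model.nucleotides:
        return []
    coords, owners = [], []
    for nt in model.nucleotides:
        for a in nt.atoms:
            coords.append(a.coord)
            owners.append(nt.ref)
    tree = cKDTree(np.array(coords))
    out: list[MgBridge] = []
    for ion in mg:
        shell: dict[tuple, float] = {}
        for idx in tree.query_ball_point(ion.coord, first_shell_cutoff):
            d = float(np.linalg.norm(np.array(coords[idx]) - ion.coord))
            if d >= first_shell_cutoff:   # enforce strict inequality
                continue
            ref = owners[idx]
            if ref not in shell or d < shell[ref]:
                shell[ref] = d
        if len(shell) >= 2:
            partners = tuple(sorted(shell))
            out.append(MgBridge(ion.id, partners,
                                tuple(shell[p] for p in partners)))
    return out


def detect_all(model: StructureModel,
               params: DetectionParams = DetectionParams()) -> ContactSet:
    """Run every detector and bundle the results with the thresholds used."""
    return ContactSet(
        base_pairs=detect_base_pairs(model, params),
        stacks=detect_stacking(model, params),
        base_phosphate=detect_base_phosphate(model, params),
        base_sugar=detect_base_sugar(model, params),
        mg_bridges=detect_mg_bridges(model, params.mg_first_shell),
        params=params,
    )
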