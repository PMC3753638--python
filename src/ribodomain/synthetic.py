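"""Ground-truth structure and alignment generators.

Everything the detection/partition/domain stages claim to measure is exercised
against assemblies built here, whose base pairs, helices, domains and
Mg²⁺ bridges are known *by construction*:

* :func:`build_aform_duplex` — an idealized A-form RNA duplex (twist 32.7°/bp,
  rise 2.81 Å/bp).  Residue geometry comes from ideal chemical-component
  coordinates; each base pair is placed by least squares onto canonical
  Watson–Crick (or wobble) hydrogen-bond distances, so every pair is a
  coplanar cis WC/WC pair and consecutive intrastrand bases stack.
* :func:`build_assembly` — multiple duplexes placed in space (explicitly or
  seeded-randomly, clash-free), with optional planted cross-helix contacts and
  first-shell Mg²⁺ bridges at exact target distances.
* :func:`synth_alignment` — sequence alignments sampled column-wise from
  specified nucleotide frequency profiles, with the analytic Shannon entropy
  of each profile available as an oracle.

All outputs are pure functions of their spec plus the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .model import Atom, IonRecord, NucleotideRecord, StructureModel

# fiber-like geometry of the idealized duplex
TWIST_DEG = 32.7
RISE = 2.81

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: base combinations accepted as a duplex pair (canonical WC + wobble)
PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

_SUGAR_PHOSPHATE = {
    "P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
    "C2'", "O2'", "C1'",
}

#: standard base reference frame coordinates (origin at the idealized pair
#: center, x toward the major groove, bases in the z=0 plane).  In this
#: convention the partner base of an ideal Watson-Crick pair occupies its own
#: standard coordinates transformed by (x, -y, -z).
_STD_BASE_FRAME = {
    "A": [
        ("N9", -1.291, 4.498), ("C8", 0.024, 4.897), ("N7", 0.877, 3.902),
        ("C5", 0.071, 2.771), ("C6", 0.369, 1.398), ("N6", 1.611, 0.909),
        ("N1", -0.668, 0.532), ("C2", -1.912, 1.023), ("N3", -2.320, 2.290),
        ("C4", -1.267, 3.124),
    ],
    "C": [
        ("N1", -1.285, 4.542), ("C2", -1.472, 3.158), ("O2", -2.628, 2.709),
        ("N3", -0.391, 2.344), ("C4", 0.837, 2.868), ("N4", 1.875, 2.027),
        ("C5", 1.056, 4.275), ("C6", -0.023, 5.068),
    ],
    "G": [
        ("N9", -1.289, 4.551), ("C8", 0.023, 4.962), ("N7", 0.870, 3.969),
        ("C5", 0.071, 2.833), ("C6", 0.424, 1.460), ("O6", 1.554, 0.955),
        ("N1", -0.700, 0.641), ("C2", -1.999, 1.087), ("N2", -2.949, 0.139),
        ("N3", -2.342, 2.364), ("C4", -1.265, 3.177),
    ],
    "U": [
        ("N1", -1.284, 4.500), ("C2", -1.462, 3.131), ("O2", -2.563, 2.608),
        ("N3", -0.302, 2.397), ("C4", 0.989, 2.884), ("O4", 1.935, 2.094),
        ("C5", 1.089, 4.311), ("C6", -0.024, 5.053),
    ],
}

# wobble pairs are sheared relative to the pure Watson-Crick arrangement and
# are refined in-plane onto these hydrogen-bond distances
_WOBBLE_TARGETS = {("G", "U"): [("O6", "N3", 2.84), ("N1", "O2", 2.83)]}


class SpecError(ValueError):
    """Invalid generator specification."""


class PlacementError(RuntimeError):
    """Clash-free placement could not be found within the retry budget."""


# ---------------------------------------------------------------------------
# residue templates and pair geometry


@lru_cache(maxsize=None)
def _ideal_residue(base: str) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Heavy-atom names, elements and ideal coordinates for a ribonucleotide."""
    import biotite.structure.info as info

    arr = info.residue(base)
    keep = [i for i, (el, nm) in enumerate(zip(arr.element, arr.atom_name))
            if el != "H" and nm != "OP3"]
    names = tuple(arr.atom_name[keep])
    elements = tuple(arr.element[keep])
    coords = np.array(arr.coord[keep], dtype=float)
    return names, elements, coords


def _rot_z(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


#: proper rotation taking a base from its own standard frame into the
#: arrangement of the partner base of an ideal pair (180° about x)
_PAIR_FLIP = np.diag([1.0, -1.0, -1.0])


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation R and translation t with P @ R.T + t ≈ Q."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


@lru_cache(maxsize=None)
def _aligned_residue(base: str) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Ideal full residue posed in the standard base reference frame."""
    names, elements, coords = _ideal_residue(base)
    idx = {n: i for i, n in enumerate(names)}
    std = _STD_BASE_FRAME[base]
    P = np.array([coords[idx[n]] for n, _, _ in std])
    Q = np.array([[x, y, 0.0] for _, x, y in std])
    R, t = _kabsch(P, Q)
    fit = P @ R.T + t
    if np.sqrt(np.mean(np.sum((fit - Q) ** 2, axis=1))) > 0.1:
        raise SpecError(f"base template for {base} does not match the standard frame")
    return names, elements, coords @ R.T + t


@lru_cache(maxsize=None)
def _pair_geometry(base_i: str, base_j: str):
    """Coordinates of an idealized coplanar pair (base_i, base_j).

    Returns (names_i, elements_i, coords_i, names_j, elements_j, coords_j)
    with the pair in the z≈0 plane and the helical axis through the origin.
    Watson-Crick combinations follow directly from the standard-frame flip;
    wobble pairs get an additional in-plane shear refined by least squares.
    """
    if (base_i, base_j) not in PAIRABLE:
        raise SpecError(f"{base_i}-{base_j} is not a pairable combination")
    names_i, el_i, ci = _aligned_residue(base_i)
    names_j, el_j, cj = _aligned_residue(base_j)
    cj = cj @ _PAIR_FLIP.T

    wobble = {base_i, base_j} == {"G", "U"}
    if wobble:
        g_first = base_i == "G"
        targets = _WOBBLE_TARGETS[("G", "U")]
        ii = {n: k for k, n in enumerate(names_i)}
        jj = {n: k for k, n in enumerate(names_j)}

        def resid(p):
            phi, tx, ty = p
            moved = cj @ _rot_z(phi).T + np.array([tx, ty, 0.0])
            out = []
            for ga, ua, d in targets:
                a, b = (ga, ua) if g_first else (ua, ga)
                pa = ci[ii[a]]
                pb = moved[jj[b]]
                out.append(np.linalg.norm(pa - pb) - d)
            # keep the backbone span at its helical value while shearing
            out.append(np.linalg.norm(ci[ii["C1'"]] - moved[jj["C1'"]]) - 10.4)
            return out

        sol = least_squares(resid, x0=[0.0, 0.0, 0.0], method="lm")
        if np.max(np.abs(resid(sol.x)[:2])) > 0.05:
            raise SpecError(f"wobble construction failed for {base_i}-{base_j}")
        phi, tx, ty = sol.x
        cj = cj @ _rot_z(phi).T + np.array([tx, ty, 0.0])
    return names_i, el_i, ci, names_j, el_j, cj


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class GroundTruth:
    """What the generator actually built, keyed by (chain, author_number) refs."""

    pairs: list = field(default_factory=list)          # list of (ref_i, ref_j) sorted tuples
    helices: list = field(default_factory=list)        # list of dicts: {"pairs": [...], "members": set}
    domain_assignment: dict = field(default_factory=dict)
    bridges: list = field(default_factory=list)        # list of frozenset of partner refs
    stacks: list = field(default_factory=list)         # intrastrand adjacent stacking truth

    def merged_with(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            pairs=self.pairs + other.pairs,
            helices=self.helices + other.helices,
            domain_assignment={**self.domain_assignment, **other.domain_assignment},
            bridges=self.bridges + other.bridges,
            stacks=self.stacks + other.stacks,
        )


# ---------------------------------------------------------------------------
# duplex builder


def build_aform_duplex(
    sequence: str,
    complement: Optional[str] = None,
    *,
    chain_ids: tuple[str, str] = ("A", "A"),
    start_i: int = 1,
    start_j: Optional[int] = None,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    orientation: Optional[np.ndarray] = None,
) -> tuple[StructureModel, GroundTruth]:
    """Build an idealized A-form duplex with known pair/helix ground truth.

    ``sequence`` is the 5'→3' first strand; ``complement`` (5'→3', same
    length) defaults to the reverse Watson–Crick complement.  The two strands
    get author numbers ``start_i..`` and ``start_j..``; residue ``k`` of the
    first strand pairs residue ``n-1-k`` of the second.
    """
    sequence = sequence.upper().replace("T", "U")
    n = len(sequence)
    if n < 2:
        raise SpecError("duplex needs at least 2 base pairs")
    if any(b not in WC_COMPLEMENT for b in sequence):
        raise SpecError(f"invalid RNA sequence {sequence!r}")
    if complement is None:
        complement = "".join(WC_COMPLEMENT[b] for b in reversed(sequence))
    complement = complement.upper().replace("T", "U")
    if len(complement) != n:
        raise SpecError("complement length mismatch")
    for k in range(n):
        if (sequence[k], complement[n - 1 - k]) not in PAIRABLE:
            raise SpecError(
                f"position {k}: {sequence[k]}-{complement[n - 1 - k]} not pairable")
    if start_j is None:
        start_j = start_i + n + 20
    R = np.eye(3) if orientation is None else np.asarray(orientation, dtype=float)
    origin = np.asarray(origin, dtype=float)

    strand1: list[NucleotideRecord] = []
    strand2: list[NucleotideRecord] = []
    twist = np.deg2rad(TWIST_DEG)
    for k in range(n):
        bi, bj = sequence[k], complement[n - 1 - k]
        names_i, el_i, ci, names_j, el_j, cj = _pair_geometry(bi, bj)
        step = _rot_z(k * twist)
        shift = np.array([0.0, 0.0, k * RISE])
        ci_w = (ci @ step.T + shift) @ R.T + origin
        cj_w = (cj @ step.T + shift) @ R.T + origin
        strand1.append(NucleotideRecord(
            chain_ids[0], start_i + k, bi,
            [Atom(nm, el, c) for nm, el, c in zip(names_i, el_i, ci_w)]))
        strand2.append(NucleotideRecord(
            chain_ids[1], start_j + (n - 1 - k), bj,
            [Atom(nm, el, c) for nm, el, c in zip(names_j, el_j, cj_w)]))

    nts = strand1 + sorted(strand2, key=lambda r: r.author_number)
    model = StructureModel(nts, source=f"synthetic duplex {sequence}")

    pairs = [tuple(sorted([strand1[k].ref, strand2[k].ref])) for k in range(n)]
    stacks = (
        [tuple(sorted([strand1[k].ref, strand1[k + 1].ref])) for k in range(n - 1)]
        + [tuple(sorted([strand2[k].ref, strand2[k + 1].ref])) for k in range(n - 1)]
    )
    truth = GroundTruth(
        pairs=sorted(pairs),
        helices=[{
            "pairs": sorted(pairs),
            "members": {nt.ref for nt in nts},
        }],
        stacks=sorted(stacks),
    )
    return model, truth


# ---------------------------------------------------------------------------
# assemblies


@dataclass
class HelixSpec:
    sequence: str
    complement: Optional[str] = None
    chain: str = "A"
    start_i: int = 1
    start_j: Optional[int] = None
    origin: Optional[Sequence[float]] = None
    orientation: Optional[np.ndarray] = None


@dataclass
class MgSite:
    partners: tuple            # two (chain, number) refs
    distance: float = 2.1      # target first-shell distance, Å


@dataclass
class PlantedContact:
    """A deliberate cross-helix atom contact realized at an exact distance."""

    ref_a: tuple
    atom_a: str
    ref_b: tuple
    atom_b: str
    distance: float = 3.0
    kind: str = "base_phosphate"


@dataclass
class AssemblySpec:
    helices: list
    planted_domains: list = field(default_factory=list)   # DomainDefinition list
    planted_contacts: list = field(default_factory=list)
    mg_sites: list = field(default_factory=list)
    seed: int = 0
    min_separation: float = 4.0
    max_tries: int = 100


def _model_coords(nts: list[NucleotideRecord]) -> np.ndarray:
    return np.concatenate([[a.coord for a in nt.atoms] for nt in nts])


def _perp_unit(e: np.ndarray) -> np.ndarray:
    v = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(v, e)) > 0.9:
        v = np.array([1.0, 0.0, 0.0])
    w = v - np.dot(v, e) * e
    return w / np.linalg.norm(w)


def bridge_candidates(a1: np.ndarray, a2: np.ndarray, d: float,
                      n_angles: int = 24) -> list[np.ndarray]:
    """Points at distance ``d`` from both a1 and a2 (circle on the bisector
    plane, sampled at ``n_angles`` positions)."""
    g = 0.5 * np.linalg.norm(a2 - a1)
    if g > d:
        raise PlacementError(
            f"bridge partners {2 * g:.2f} Å apart cannot both be at {d:.2f} Å")
    e = (a2 - a1) / (2 * g) if g > 0 else np.array([1.0, 0.0, 0.0])
    mid = 0.5 * (a1 + a2)
    h = np.sqrt(max(d * d - g * g, 0.0))
    w1 = _perp_unit(e)
    w2 = np.cross(e, w1)
    thetas = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    return [mid + h * (np.cos(t) * w1 + np.sin(t) * w2) for t in thetas]


def build_assembly(spec: AssemblySpec) -> tuple[StructureModel, GroundTruth]:
    """Place the spec's helices clash-free and realize planted contacts/bridges."""
    if not spec.helices:
        raise SpecError("assembly needs at least one helix")
    rng = np.random.default_rng(spec.seed)

    placed_nts: list[NucleotideRecord] = []
    truth = GroundTruth()
    ref_to_nt: dict = {}

    contact_for_helix: dict[int, PlantedContact] = {}
    for pc in spec.planted_contacts:
        for h_idx, hs in enumerate(spec.helices):
            if _helix_owns(hs, pc.ref_b):
                contact_for_helix[h_idx] = pc
    # a cross-helix Mg site constrains placement too: pose the later helix so
    # the partner residues come close enough to share a first-shell ion
    for site in spec.mg_sites:
        owners = []
        for r in site.partners:
            for h_idx, hs in enumerate(spec.helices):
                if _helix_owns(hs, tuple(r)):
                    owners.append((h_idx, tuple(r)))
                    break
        if len(owners) == 2 and owners[0][0] != owners[1][0]:
            (early, ref_a), (late, ref_b) = sorted(owners)
            if late not in contact_for_helix:
                contact_for_helix[late] = PlantedContact(
                    ref_a=ref_a, atom_a="OP2", ref_b=ref_b, atom_b="OP2",
                    distance=1.7 * site.distance, kind="mg_proximity")

    for h_idx, hs in enumerate(spec.helices):
        local_model, local_truth = build_aform_duplex(
            hs.sequence, hs.complement, chain_ids=(hs.chain, hs.chain),
            start_i=hs.start_i, start_j=hs.start_j)
        local_coords = _model_coords(local_model.nucleotides)

        if hs.origin is not None or h_idx == 0:
            R = np.eye(3) if hs.orientation is None else np.asarray(hs.orientation)
            t = np.zeros(3) if hs.origin is None else np.asarray(hs.origin, float)
            _apply_rigid(local_model, R, t)
            _check_clash(local_model, placed_nts, spec, contact_for_helix.get(h_idx))
        else:
            _place_random(local_model, local_coords, placed_nts, spec, rng,
                          contact_for_helix.get(h_idx), ref_to_nt)

        placed_nts.extend(local_model.nucleotides)
        for nt in local_model.nucleotides:
            ref_to_nt[nt.ref] = nt
        truth = truth.merged_with(local_truth)

    ions = []
    all_coords = []
    all_owners = []
    for nt in placed_nts:
        for a in nt.atoms:
            all_coords.append(a.coord)
            all_owners.append(nt.ref)
    all_coords = np.array(all_coords)
    all_owners = np.array(all_owners, dtype=object)
    first_shell = 2.6  # default detection cutoff the truth must be clean under
    for k, site in enumerate(spec.mg_sites, start=1):
        if len(site.partners) < 2:
            raise SpecError("Mg site needs >= 2 partner residues")
        partner_set = {tuple(r) for r in site.partners}
        nts = [ref_to_nt[tuple(r)] for r in site.partners]
        is_partner = np.array([tuple(o) in partner_set for o in all_owners])
        # the nearest approach to each partner must be exactly the target and
        # no other residue may intrude into the first shell, so cutoff-flip
        # behaviour and the bridge partner set are both well defined
        pos = None
        other_floor = max(site.distance, first_shell) + 0.05
        for a1, a2 in _ligand_atom_pairs(nts[0], nts[1], site.distance):
            for cand in bridge_candidates(a1, a2, site.distance):
                d_all = np.linalg.norm(all_coords - cand, axis=1)
                if (d_all[is_partner].min() >= site.distance - 1e-6
                        and d_all[~is_partner].min() >= other_floor):
                    pos = cand
                    break
            if pos is not None:
                break
        if pos is None:
            raise PlacementError(
                f"no clean first-shell position for Mg site {site.partners}")
        ions.append(IonRecord("MG", pos, id=f"MG{k}"))
        truth.bridges.append(frozenset(tuple(r) for r in site.partners))

    for dd in spec.planted_domains:
        for nt in placed_nts:
            if any(lo <= nt.author_number <= hi for lo, hi in dd.ranges):
                truth.domain_assignment[nt.ref] = dd.label

    model = StructureModel(placed_nts, ions, source=f"synthetic assembly seed={spec.seed}")
    return model, truth


def _helix_owns(hs: HelixSpec, ref: tuple) -> bool:
    n = len(hs.sequence)
    sj = hs.start_j if hs.start_j is not None else hs.start_i + n + 20
    chain, num = ref
    return chain == hs.chain and (
        hs.start_i <= num < hs.start_i + n or sj <= num < sj + n)


def _apply_rigid(model: StructureModel, R: np.ndarray, t: np.ndarray) -> None:
    for nt in model.nucleotides:
        nt.atoms = [Atom(a.name, a.element, R @ a.coord + t) for a in nt.atoms]


def _ligand_atom_pairs(nt1: NucleotideRecord, nt2: NucleotideRecord, d: float):
    """O/N atom pairs between two residues close enough to share an Mg at
    distance ``d``, nearest first."""
    def cands(nt):
        return np.array([a.coord for a in nt.atoms if a.element in ("O", "N")])
    c1, c2 = cands(nt1), cands(nt2)
    sep = cdist(c1, c2)
    order = np.dstack(np.unravel_index(np.argsort(sep, axis=None), sep.shape))[0]
    return [(c1[i], c2[j]) for i, j in order if sep[i, j] <= 2 * d]


HARD_CLASH = 2.2        # Å; planted-contact residues may approach but not overlap
DETECTION_FLOOR = 3.6   # Å; just above the H-bond cutoff, so the only detected
                        # cross-helix contacts are the planted ones


_CONTACT_RADIUS = 10.0  # Å around a planted contact where only hard clash applies


def _clash_free(new_coords, old_coords, spec,
                contact_point: Optional[np.ndarray]) -> bool:
    """min_separation between helices; near a planted contact only a
    hard-sphere floor applies (a genuine inter-helix junction brings whole
    residue neighbourhoods together), while every atom pair outside the
    junction stays beyond hydrogen-bond detection range."""
    D = cdist(new_coords, old_coords)
    if contact_point is None:
        return bool(D.min() > spec.min_separation)
    dn = np.linalg.norm(new_coords - contact_point, axis=1)
    do = np.linalg.norm(old_coords - contact_point, axis=1)
    near = (dn[:, None] < _CONTACT_RADIUS) | (do[None, :] < _CONTACT_RADIUS)
    floor = np.where(near, HARD_CLASH, DETECTION_FLOOR)
    return bool((D > floor).all())


def _check_clash(model, placed_nts, spec, planted: Optional[PlantedContact]) -> None:
    if not placed_nts:
        return
    cp = None
    if planted is not None:
        allnts = list(model.nucleotides) + list(placed_nts)
        pts = []
        for ref, name in ((tuple(planted.ref_a), planted.atom_a),
                          (tuple(planted.ref_b), planted.atom_b)):
            for nt in allnts:
                if nt.ref == ref and nt.coord(name) is not None:
                    pts.append(nt.coord(name))
        cp = np.mean(pts, axis=0) if pts else None
    if not _clash_free(_model_coords(model.nucleotides), _model_coords(placed_nts),
                       spec, cp):
        raise PlacementError("explicit placement clashes with existing helices")


def _rotation_between(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector v1 onto unit vector v2."""
    c = float(np.dot(v1, v2))
    axis = np.cross(v1, v2)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        if c > 0:
            return np.eye(3)
        axis = _perp_unit(v1)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis /= norm
    return Rotation.from_rotvec(np.arccos(np.clip(c, -1, 1)) * axis).as_matrix()


def _place_random(model, local_coords, placed_nts, spec, rng, planted, ref_to_nt):
    if not placed_nts:
        return
    old_all = _model_coords(placed_nts)
    if planted is not None:
        target = ref_to_nt[tuple(planted.ref_a)].coord(planted.atom_a)
        if target is None:
            raise SpecError(f"atom {planted.atom_a} absent on {planted.ref_a}")
        local_b = None
        for nt in model.nucleotides:
            if nt.ref == tuple(planted.ref_b):
                local_b = nt.coord(planted.atom_b)
        if local_b is None:
            raise SpecError(f"atom {planted.atom_b} absent on {planted.ref_b}")
        # candidate outward directions on each side: radial from the helix
        # axis, the two axial cap directions, and centroid-to-atom; the helix
        # axes are estimated by PCA.  Docking along opposed outward directions
        # keeps the two bodies tangent at the planted contact.
        def outward_candidates(coords, atom):
            centered = coords - coords.mean(axis=0)
            axis = np.linalg.svd(centered, full_matrices=False)[2][0]
            rel = atom - coords.mean(axis=0)
            radial = rel - np.dot(rel, axis) * axis
            cands = []
            if np.linalg.norm(radial) > 1e-6:
                cands.append(radial / np.linalg.norm(radial))
            cands.extend([axis, -axis])
            if np.linalg.norm(rel) > 1e-6:
                cands.append(rel / np.linalg.norm(rel))
            return cands

        spins = rng.uniform(0, 2 * np.pi, size=12)
        for out_a in outward_candidates(old_all, target):
            for out_b in outward_candidates(local_coords, local_b):
                R0 = _rotation_between(out_b, -out_a)
                for theta in spins:
                    R = Rotation.from_rotvec(theta * out_a).as_matrix() @ R0
                    t = target + planted.distance * out_a - R @ local_b
                    moved = local_coords @ R.T + t
                    cp = 0.5 * (target + (R @ local_b + t))
                    if _clash_free(moved, old_all, spec, cp):
                        _apply_rigid(model, R, t)
                        return
    else:
        for _ in range(spec.max_tries):
            R = Rotation.random(random_state=rng).as_matrix()
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            t = old_all.mean(axis=0) + u * rng.uniform(30.0, 70.0)
            moved = local_coords @ R.T + t
            if cdist(moved, old_all).min() > spec.min_separation:
                _apply_rigid(model, R, t)
                return
    raise PlacementError(f"no clash-free placement found in {spec.max_tries} tries")


# ---------------------------------------------------------------------------
# alignments


def analytic_entropy(profile: Sequence[float]) -> float:
    """Shannon entropy (bits) of a 4-vector nucleotide profile."""
    p = np.asarray(profile, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def synth_alignment(profiles: Sequence[Sequence[float]], n_rows: int, seed: int = 0):
    """Sample an alignment whose column ``c`` draws i.i.d. from ``profiles[c]``.

    Returns a Biopython MultipleSeqAlignment; rows are named ``seq0001`` …
    """
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGU"))
    cols = []
    for c, prof in enumerate(profiles):
        p = np.asarray(prof, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise SpecError(f"column {c}: profile must be 4 non-negative values summing to 1")
        cols.append(alphabet[rng.choice(4, size=n_rows, p=p)])
    mat = np.stack(cols, axis=1)
    records = [
        SeqRecord(Seq("".join(row)), id=f"seq{i + 1:04d}", description="")
        for i, row in enumerate(mat)
    ]
    return MultipleSeqAlignment(records)
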