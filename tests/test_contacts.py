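"""Geometric contact detection: pairs, edges, stacking, backbone, Mg bridges."""

import numpy as np
import pytest

from ribodomain.contacts import (DetectionParams, classify_edge,
                                 ClassificationError, detect_all,
                                 detect_base_pairs, detect_base_phosphate,
                                 detect_base_sugar, detect_mg_bridges,
                                 detect_stacking)
from ribodomain.model import Atom, IonRecord, NucleotideRecord, StructureModel
from ribodomain.synthetic import (AssemblySpec, HelixSpec, MgSite,
                                  build_aform_duplex, build_assembly)


def pair_keys(pairs):
    return sorted(tuple(sorted((p.nt_i, p.nt_j))) for p in pairs)


# ---------------------------------------------------------------------------
# base pairs


def test_ideal_duplex_detects_all_pairs_canonical(duplex8, duplex8_contacts):
    _, truth = duplex8
    pairs = duplex8_contacts.base_pairs
    assert pair_keys(pairs) == truth.pairs
    assert all(p.canonical and p.lw_class == "cWW" for p in pairs)
    # independent check: every pair has >= 2 hydrogen-bond-range contacts
    assert all(p.hbond_count >= 2 and p.hbond_mean_dist <= 3.5 for p in pairs)


def test_far_apart_nucleotides_do_not_pair():
    m1, _ = build_aform_duplex("GC", start_i=1, start_j=11)
    m2, _ = build_aform_duplex("AU", start_i=21, start_j=31,
                               origin=(60.0, 0.0, 0.0))
    merged = StructureModel(m1.nucleotides + m2.nucleotides)
    pairs = detect_base_pairs(merged)
    crossing = [p for p in pairs
                if (p.nt_i[1] < 20) != (p.nt_j[1] < 20)]
    assert crossing == []


def test_wobble_duplex_pairs_detected():
    model, truth = build_aform_duplex("GGUAGUCC", complement="GGGCUGCC")
    pairs = detect_base_pairs(model)
    assert pair_keys(pairs) == truth.pairs
    assert all(p.canonical for p in pairs)


def test_biotite_crosscheck_on_duplex(tmp_path, duplex8):
    """Independent detector (biotite's base_pairs) finds the same 8 pairs."""
    import biotite.structure.io.pdb as bpdb
    from biotite.structure import base_pairs as bt_base_pairs

    from ribodomain.structure_io import write_structure

    model, truth = duplex8
    path = tmp_path / "duplex.pdb"
    write_structure(model, path, "pdb")
    arr = bpdb.PDBFile.read(str(path)).get_structure(model=1)
    hits = bt_base_pairs(arr)
    found = sorted(tuple(sorted((int(arr.res_id[i]), int(arr.res_id[j]))))
                   for i, j in hits)
    expected = sorted((a[1], b[1]) for a, b in truth.pairs)
    assert found == expected


def test_pair_detection_monotone_in_hbond_cutoff(duplex8):
    model, _ = duplex8
    loose = detect_base_pairs(model, DetectionParams(hbond_max=3.5))
    tight = detect_base_pairs(model, DetectionParams(hbond_max=3.0))
    assert set(pair_keys(tight)) <= set(pair_keys(loose))


def test_pair_classification_robust_to_coordinate_noise(duplex8):
    model, truth = duplex8
    rng = np.random.default_rng(42)
    for _ in range(5):
        noisy_nts = [
            NucleotideRecord(nt.chain_id, nt.author_number, nt.base_type,
                             [Atom(a.name, a.element,
                                   a.coord + rng.normal(scale=0.1, size=3))
                              for a in nt.atoms])
            for nt in model.nucleotides]
        pairs = detect_base_pairs(StructureModel(noisy_nts))
        assert pair_keys(pairs) == truth.pairs
        assert all(p.canonical and p.lw_class == "cWW" for p in pairs)


# ---------------------------------------------------------------------------
# edges


@pytest.mark.parametrize("base,atoms,expected", [
    ("A", ["N1", "C2"], "WatsonCrick"),
    ("A", ["N7", "N6"], "Hoogsteen"),
    ("G", ["N3", "O2'"], "SugarEdge"),
    ("G", ["O6", "N1", "N2"], "WatsonCrick"),
    ("U", ["O4", "N3"], "WatsonCrick"),
    ("C", ["O2", "O2'"], "SugarEdge"),
])
def test_edge_classification_table(base, atoms, expected):
    assert classify_edge(base, atoms) == expected


def test_edge_classification_requires_contact_atoms():
    with pytest.raises(ClassificationError):
        classify_edge("A", [])


# ---------------------------------------------------------------------------
# stacking


def test_duplex_intrastrand_stacking_complete(duplex8, duplex8_contacts):
    _, truth = duplex8
    got = {tuple(sorted((s.nt_i, s.nt_j))) for s in duplex8_contacts.stacks}
    # all 14 sequence-adjacent intrastrand neighbour stacks present ...
    assert set(truth.stacks) <= got
    # ... and they are the only intrastrand stacks in a straight duplex
    def strand(ref):
        return 0 if ref[1] <= 20 else 1
    intrastrand = {g for g in got if strand(g[0]) == strand(g[1])}
    assert intrastrand == set(truth.stacks)
    assert len(truth.stacks) == 14


def _planar_base(number, shift, chain="A"):
    """A bare guanine base translated rigidly by `shift`."""
    from ribodomain.synthetic import _aligned_residue
    names, elements, coords = _aligned_residue("G")
    atoms = [Atom(n, e, c + np.asarray(shift, float))
             for n, e, c in zip(names, elements, coords)]
    return NucleotideRecord(chain, number, "G", atoms)


def test_coplanar_side_by_side_bases_do_not_stack():
    model = StructureModel([_planar_base(1, (0, 0, 0)), _planar_base(2, (6.0, 0, 0))])
    assert detect_stacking(model) == []


def test_parallel_offset_bases_stack():
    model = StructureModel([_planar_base(1, (0, 0, 0)), _planar_base(2, (0, 0, 3.4))])
    stacks = detect_stacking(model)
    assert len(stacks) == 1
    s = stacks[0]
    assert s.vertical_sep == pytest.approx(3.4, abs=0.01)
    assert s.overlap_area > 0


def test_stack_lists_are_deduplicated(duplex8_contacts):
    keys = [tuple(sorted((s.nt_i, s.nt_j))) for s in duplex8_contacts.stacks]
    assert len(keys) == len(set(keys))


# ---------------------------------------------------------------------------
# base-phosphate / base-sugar


def _res_with_atoms(number, atoms, base="G", chain="A"):
    return NucleotideRecord(chain, number, base,
                            [Atom(n, e, np.asarray(c, float)) for n, e, c in atoms])


def _gua_with_op2(number, n2_pos, op2_offset):
    """Guanine with its N2 at n2_pos plus a distant residue's OP2."""
    donor = _planar_base(number, np.asarray(n2_pos) - 0.0)
    return donor


def _outward_from_n2(donor, dist):
    """A point `dist` beyond N2 along the centroid->N2 direction (away from
    every other base atom)."""
    n2 = donor.coord("N2")
    centroid = np.mean([a.coord for a in donor.atoms], axis=0)
    u = (n2 - centroid) / np.linalg.norm(n2 - centroid)
    return n2 + dist * u


def test_base_phosphate_contact_within_cutoff():
    donor = _planar_base(1, (0, 0, 0))
    acceptor = _res_with_atoms(40, [("OP2", "O", _outward_from_n2(donor, 3.0))])
    hits = detect_base_phosphate(StructureModel([donor, acceptor]))
    assert [(c.donor, c.acceptor) for c in hits] == [(("A", 1), ("A", 40))]
    assert hits[0].distance == pytest.approx(3.0, abs=1e-6)
    assert hits[0].donor_atom == "N2" and hits[0].acceptor_atom == "OP2"


def test_base_phosphate_beyond_cutoff_not_detected():
    donor = _planar_base(1, (0, 0, 0))
    acceptor = _res_with_atoms(40, [("OP2", "O", _outward_from_n2(donor, 4.0))])
    assert detect_base_phosphate(StructureModel([donor, acceptor])) == []


def test_contact_to_own_phosphate_excluded():
    base = _planar_base(1, (0, 0, 0))
    n2 = base.coord("N2")
    base.atoms.append(Atom("OP2", "O", n2 + [3.0, 0, 0]))
    assert detect_base_phosphate(StructureModel([base])) == []


def test_base_sugar_contact():
    donor = _planar_base(1, (0, 0, 0))
    n2 = donor.coord("N2")
    acceptor = _res_with_atoms(40, [("O2'", "O", n2 + [3.0, 0, 0])])
    hits = detect_base_sugar(StructureModel([donor, acceptor]))
    assert len(hits) == 1 and hits[0].acceptor_atom == "O2'"


# ---------------------------------------------------------------------------
# Mg bridges


def _mg_model(d1, d2):
    r1 = _res_with_atoms(5, [("OP1", "O", (-d1, 0, 0))])
    r2 = _res_with_atoms(40, [("OP2", "O", (d2, 0, 0))])
    ion = IonRecord("MG", np.zeros(3), "MG1")
    return StructureModel([r1, r2], [ion])


def test_mg_bridge_within_first_shell():
    bridges = detect_mg_bridges(_mg_model(2.1, 2.1))
    assert len(bridges) == 1
    assert bridges[0].partners == (("A", 5), ("A", 40))


def test_mg_cutoff_is_strict():
    assert detect_mg_bridges(_mg_model(2.7, 2.7)) == []
    # just inside the cutoff on both sides -> bridge
    assert detect_mg_bridges(_mg_model(2.59, 2.59)) != []
    # exactly at the cutoff fails the strict inequality
    assert detect_mg_bridges(_mg_model(2.6, 2.6)) == []
    # one partner at the cutoff leaves a single in-shell residue: no bridge
    assert detect_mg_bridges(_mg_model(2.6, 2.1)) == []


def test_mg_needs_two_partner_residues():
    r1 = _res_with_atoms(5, [("OP1", "O", (2.1, 0, 0))])
    model = StructureModel([r1], [IonRecord("MG", np.zeros(3), "MG1")])
    assert detect_mg_bridges(model) == []


def test_mg_bridge_monotone_in_cutoff(three_helix_assembly):
    model, _ = three_helix_assembly
    wide = {b.ion_id for b in detect_mg_bridges(model, 2.6)}
    narrow = {b.ion_id for b in detect_mg_bridges(model, 2.0)}
    assert narrow <= wide


# ---------------------------------------------------------------------------
# cross-cutting


def test_contact_set_records_parameters(duplex8_contacts):
    params = duplex8_contacts.params_dict()
    assert params["mg_first_shell"] == 2.6
    assert params["hbond_max"] == 3.5


def test_empty_model_yields_empty_contacts():
    cset = detect_all(StructureModel([_planar_base(1, (0, 0, 0))]))
    assert cset.base_pairs == [] and cset.mg_bridges == []
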