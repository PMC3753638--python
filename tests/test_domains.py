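"""Domain assignment, interaction matrices, boundary refinement, fold export."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ribodomain.contacts import AtomContact, BasePair, ContactSet, MgBridge
from ribodomain.domains import (DefinitionError, DomainDefinition, DomainModel,
                                ExclusionPolicy, IntegrityError,
                                assign_domains, check_definitions,
                                domain0_interlock_report,
                                export_foldable_sequence, interaction_matrix,
                                load_domain_definitions, refine_boundaries,
                                scale_matrix)
from ribodomain.model import Atom, NucleotideRecord, StructureModel


def _chain_model(numbers, chain="A", base="A"):
    """Minimal nucleotides (one placeholder atom each) for assignment tests."""
    nts = [NucleotideRecord(chain, n, base,
                            [Atom("C1'", "C", np.array([float(n), 0.0, 0.0]))])
           for n in numbers]
    return StructureModel(nts)


def _pair(i, j, chain="A", hbonds=2):
    a, b = sorted([(chain, i), (chain, j)])
    return BasePair(a, b, "A", "U", "WatsonCrick", "WatsonCrick", "cis", True,
                    hbonds, 2.9)


THREED7 = [
    DomainDefinition("0", ((562, 586), (1251, 1270), (1648, 1678),
                           (1990, 2057), (2611, 2625))),
    DomainDefinition("I", ((1, 561), (2895, 2904))),
    DomainDefinition("II", ((587, 1250),)),
    DomainDefinition("III", ((1271, 1647),)),
    DomainDefinition("IV", ((1679, 1989),)),
    DomainDefinition("V", ((2058, 2610),)),
    DomainDefinition("VI", ((2626, 2894),)),
]


class TestAssignment:
    def test_seven_domain_model_core_domain_size(self):
        """The central core domain of the seven-domain architecture collects
        159 nucleotides on a complete 1..2904 chain (oracle: direct range
        arithmetic, 25+20+31+68+15)."""
        model = _chain_model(range(1, 2905))
        dm = assign_domains(model, THREED7, name="threeD7")
        assert dm.n_per_domain["0"] == 159
        assert sum(dm.n_per_domain.values()) == 2904
        assert dm.unassigned == []

    def test_single_domain_covers_everything(self):
        model = _chain_model(range(1, 51))
        dm = assign_domains(model, [DomainDefinition("all", ((1, 100),))])
        assert set(dm.assignment.values()) == {"all"}

    def test_overlapping_definitions_rejected(self):
        with pytest.raises(DefinitionError, match="overlap"):
            check_definitions([DomainDefinition("a", ((562, 586),)),
                               DomainDefinition("b", ((580, 600),))])

    def test_gaps_reported_not_dropped(self):
        model = _chain_model([1, 2, 99])
        dm = assign_domains(model, [DomainDefinition("a", ((1, 10),))])
        assert dm.unassigned == [("A", 99)]

    def test_bundled_definition_table_loads(self):
        from importlib.resources import files

        path = files("ribodomain").joinpath("data/domains_threeD7.csv")
        defs = load_domain_definitions(str(path))
        assert [d.label for d in defs] == ["0", "I", "II", "III", "IV", "V", "VI"]
        assert defs[0].size == 159


class TestInteractionMatrix:
    def _toy(self, cross_pairs=3, intra_pairs=0):
        model = _chain_model(range(1, 41))
        defs = [DomainDefinition("D1", ((1, 10),)),
                DomainDefinition("D2", ((11, 40),))]
        dm = assign_domains(model, defs)
        pairs = [_pair(i, 11 + i) for i in range(1, cross_pairs + 1)]
        pairs += [_pair(2 * k + 1, 2 * k + 2) for k in range(intra_pairs)]
        return dm, ContactSet(base_pairs=pairs)

    def test_cross_domain_scaling(self):
        dm, cset = self._toy(cross_pairs=3)
        mat = interaction_matrix(dm, cset)
        assert mat.raw[0, 1] == 3
        assert mat.scaled[0, 1] == pytest.approx(3 / 20)

    def test_intra_domain_scaling(self):
        dm, cset = self._toy(cross_pairs=0, intra_pairs=5)
        mat = interaction_matrix(dm, cset)
        assert mat.raw[0, 0] == 5
        assert mat.scaled[0, 0] == pytest.approx(0.5)

    def test_empty_contacts_zero_matrix(self):
        dm, _ = self._toy()
        mat = interaction_matrix(dm, ContactSet())
        assert mat.raw.sum() == 0 and mat.scaled.sum() == 0

    def test_secondary_pairs_excluded_by_policy(self):
        dm, cset = self._toy(cross_pairs=3)
        keys = frozenset(p.key for p in cset.base_pairs[:2])
        mat = interaction_matrix(dm, cset, ExclusionPolicy(secondary_pair_keys=keys))
        assert mat.raw[0, 1] == 1
        assert mat.excluded["secondary_pairs"] == 2

    def test_mg_bridge_contributes_partner_pairs(self):
        dm, _ = self._toy()
        bridge = MgBridge("MG1", (("A", 1), ("A", 5), ("A", 20)), (2.1, 2.2, 2.3))
        mat = interaction_matrix(dm, ContactSet(mg_bridges=[bridge]))
        # C(3,2)=3 partner pairs: (1,5) intra-D1, (1,20) and (5,20) cross
        assert mat.raw[0, 0] == 1 and mat.raw[0, 1] == 2

    def test_unassigned_nucleotide_raises_integrity_error(self):
        model = _chain_model([1, 2])
        dm = assign_domains(model, [DomainDefinition("a", ((1, 1),))])
        with pytest.raises(IntegrityError):
            interaction_matrix(dm, ContactSet(base_pairs=[_pair(1, 2)]))

    def test_scaling_identities_on_random_contact_sets(self):
        """scaled(i,i) = raw(i,i)/N_i and scaled(i,j) = raw(i,j)/((N_i+N_j)/2)
        hold exactly for random symmetric count matrices."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            d = int(rng.integers(2, 8))
            sizes = rng.integers(5, 400, size=d)
            raw = rng.integers(0, 50, size=(d, d))
            raw = raw + raw.T
            scaled = scale_matrix(raw, sizes)
            for i in range(d):
                assert scaled[i, i] == pytest.approx(raw[i, i] / sizes[i])
                for j in range(i + 1, d):
                    assert scaled[i, j] == pytest.approx(
                        raw[i, j] / ((sizes[i] + sizes[j]) / 2))
                    assert scaled[i, j] == scaled[j, i]

    def test_total_raw_conserved_across_repartition(self):
        """Re-partitioning moves interactions between intra and inter cells but
        never changes the total count."""
        rng = np.random.default_rng(1)
        model = _chain_model(range(1, 61))
        pairs = []
        seen = set()
        while len(pairs) < 25:
            i, j = sorted(rng.integers(1, 61, size=2))
            if i != j and (i, j) not in seen:
                seen.add((i, j))
                pairs.append(_pair(i, j))
        cset = ContactSet(base_pairs=pairs)

        def total(mat):
            return int(np.trace(mat.raw)) + int(
                (mat.raw.sum() - np.trace(mat.raw)) // 2)

        cuts = [20, 30, 45]
        totals = []
        for cut in cuts:
            dm = assign_domains(model, [DomainDefinition("L", ((1, cut),)),
                                        DomainDefinition("R", ((cut + 1, 60),))])
            totals.append(total(interaction_matrix(dm, cset)))
        assert len(set(totals)) == 1 == len({totals[0], 25})

    def test_diagonal_dominance_on_dense_intra_contacts(self):
        """When intra-domain contact density exceeds cross-domain density the
        scaled diagonal dominates its row."""
        rng = np.random.default_rng(5)
        model = _chain_model(range(1, 81))
        defs = [DomainDefinition("D1", ((1, 40),)),
                DomainDefinition("D2", ((41, 80),))]
        dm = assign_domains(model, defs)
        pairs = []
        used = set()

        def add_pair(lo, hi, n):
            while n:
                i, j = sorted(rng.integers(lo, hi + 1, size=2))
                if i != j and (i, j) not in used:
                    used.add((i, j))
                    pairs.append(_pair(i, j))
                    n -= 1

        add_pair(1, 40, 30)
        add_pair(41, 80, 30)
        # sparse cross contacts
        for _ in range(4):
            i = int(rng.integers(1, 41))
            j = int(rng.integers(41, 81))
            if (i, j) not in used:
                used.add((i, j))
                pairs.append(_pair(i, j))
        mat = interaction_matrix(dm, ContactSet(base_pairs=pairs))
        for i in range(2):
            for j in range(2):
                if i != j:
                    assert mat.scaled[i, i] > mat.scaled[i, j]


class TestRefinement:
    def _planted(self, boundary, pairs_within=12, seed=0):
        """Two-domain chain 1..60 with contacts only within the planted halves."""
        rng = np.random.default_rng(seed)
        model = _chain_model(range(1, 61))
        pairs, used = [], set()

        def sample(lo, hi, n):
            while n:
                i, j = sorted(rng.integers(lo, hi + 1, size=2))
                if j - i >= 2 and (i, j) not in used:
                    used.add((i, j))
                    pairs.append(_pair(i, j))
                    n -= 1

        sample(1, 30, pairs_within)
        sample(31, 60, pairs_within)
        # every nucleotide near the true boundary is networked into its half,
        # as rRNA nucleotides are
        for n in range(24, 31):
            if (n - 12, n) not in used:
                used.add((n - 12, n))
                pairs.append(_pair(n - 12, n))
        for n in range(31, 38):
            if (n, n + 12) not in used:
                used.add((n, n + 12))
                pairs.append(_pair(n, n + 12))
        dm = assign_domains(model, [DomainDefinition("L", ((1, boundary),)),
                                    DomainDefinition("R", ((boundary + 1, 60),))])
        return dm, ContactSet(base_pairs=pairs)

    def test_perturbed_boundary_restored(self):
        dm, cset = self._planted(boundary=27, seed=3)
        refined = refine_boundaries(dm, cset)
        labels = [refined.assignment[("A", n)] for n in range(1, 61)]
        assert labels == ["L"] * 30 + ["R"] * 30

    def test_fixed_point_when_already_optimal(self):
        dm, cset = self._planted(boundary=30, seed=4)
        refined = refine_boundaries(dm, cset)
        assert refined.assignment == dm.assignment

    def test_objective_monotone_non_increasing(self):
        from ribodomain.domains import (DEFAULT_PRIORITY_WEIGHTS,
                                        _contact_items, _weighted_interdomain)

        dm, cset = self._planted(boundary=33, seed=5)
        items = _contact_items(cset, DEFAULT_PRIORITY_WEIGHTS, frozenset())
        before = _weighted_interdomain(items, dm.assignment)
        refined = refine_boundaries(dm, cset)
        after = _weighted_interdomain(items, refined.assignment)
        assert after <= before

    def test_helix_split_move_rejected(self):
        """A move that would separate a helix's members across two domains is
        illegal even when it would reduce the objective."""
        from ribodomain.helices import Helix, HelixPartition

        model = _chain_model(range(1, 21))
        dm = assign_domains(model, [DomainDefinition("L", ((1, 10),)),
                                    DomainDefinition("R", ((11, 20),))])
        # nucleotide 10 pairs into domain R: moving it would help, but it is
        # part of a helix 7..10 that must stay intact in L
        cross = [_pair(10, 15), _pair(10, 16, hbonds=3)]
        helix = Helix("H1", [ _pair(7, 8), _pair(9, 10)],
                      members={("A", 7), ("A", 8), ("A", 9), ("A", 10)})
        part = HelixPartition([helix], [])
        cset = ContactSet(base_pairs=cross)
        refined = refine_boundaries(dm, cset, helix_partition=part)
        assert refined.assignment[("A", 10)] == "L"
        # without the helix constraint the nucleotide moves
        free = refine_boundaries(dm, cset)
        assert free.assignment[("A", 10)] == "R"


class TestInterlockReport:
    def _partition(self):
        from ribodomain.helices import Helix, HelixPartition

        h1 = Helix("26a", [_pair(1, 18), _pair(2, 17)],
                   members={("A", 1), ("A", 2), ("A", 17), ("A", 18)})
        h2 = Helix("61", [_pair(30, 48), _pair(31, 47)],
                   members={("A", 30), ("A", 31), ("A", 47), ("A", 48)})
        return HelixPartition([h1, h2], [])

    def test_single_base_sugar_interlock_counted(self):
        part = self._partition()
        contact = AtomContact(("A", 2), ("A", 30), "N1", "O2'", 3.1)
        df = domain0_interlock_report(part, ContactSet(base_sugar=[contact]),
                                      ["26a", "61"])
        row = df.iloc[0]
        assert (row["helix_i"], row["helix_j"]) == ("26a", "61")
        assert row["base_backbone"] == 1 and row["total"] == 1

    def test_no_mutual_contacts_all_zero(self):
        part = self._partition()
        df = domain0_interlock_report(part, ContactSet(), ["26a", "61"])
        assert (df["total"] == 0).all()

    def test_own_secondary_pairs_do_not_count(self):
        part = self._partition()
        cset = ContactSet(base_pairs=[_pair(1, 18), _pair(30, 48)])
        df = domain0_interlock_report(part, cset, ["26a", "61"])
        assert (df["total"] == 0).all()

    def test_mg_bridge_between_helices_counted(self):
        part = self._partition()
        bridge = MgBridge("MG1", (("A", 2), ("A", 31)), (2.2, 2.3))
        df = domain0_interlock_report(part, ContactSet(mg_bridges=[bridge]),
                                      ["26a", "61"])
        assert df.iloc[0]["mg"] == 1

    def test_unknown_helix_name_raises(self):
        with pytest.raises(KeyError):
            domain0_interlock_report(self._partition(), ContactSet(), ["26a", "99"])


class TestFoldableExport:
    def _model(self, sequence, start=1):
        nts = [NucleotideRecord("A", start + k, b,
                                [Atom("C1'", "C", np.array([float(k), 0, 0]))])
               for k, b in enumerate(sequence)]
        return StructureModel(nts)

    def test_fragments_joined_with_linker_positions(self):
        model = self._model("ACGUGGCC")   # numbers 1..8
        domain = DomainDefinition("d", ((1, 4), (5, 8)))
        fs = export_foldable_sequence(model, domain)
        assert fs.sequence == "ACGUGGCC"
        assert fs.linker_positions == [4]

    def test_substitution_replaces_range_any_length(self):
        model = self._model("ACGUGGCC")
        domain = DomainDefinition("d", ((1, 8),))
        fs = export_foldable_sequence(model, domain,
                                      substitutions=[((5, 8), "GUAUAUGC")])
        assert fs.sequence == "ACGUGUAUAUGC"
        assert fs.substitutions == [((5, 8), "GUAUAUGC")]

    def test_substitution_outside_domain_rejected(self):
        model = self._model("ACGU")
        domain = DomainDefinition("d", ((1, 4),))
        with pytest.raises(DefinitionError):
            export_foldable_sequence(model, domain,
                                     substitutions=[((10, 12), "GGG")])

    def test_core_domain_fragment_order_with_helix_substitution(self):
        """Fragments concatenate in ascending range order; the non-canonical
        central helix strands are swapped for the canonical duplex strands."""
        rng = np.random.default_rng(11)
        seq = rng.choice(list("ACGU"), size=2904)
        nts = [NucleotideRecord("A", k + 1, seq[k],
                                [Atom("C1'", "C", np.array([float(k), 0, 0]))])
               for k in range(2904)]
        model = StructureModel(nts)
        fs = export_foldable_sequence(
            model, THREED7[0],
            substitutions=[((1262, 1270), "GUAUAUGC"),
                           ((2010, 2017), "GCAUAUAC")])
        # 159 original nt, minus 9+8 substituted out, plus 8+8 substituted in
        assert len(fs.sequence) == 159 - 17 + 16
        assert len(fs.linker_positions) == 4
        assert "GUAUAUGC" in fs.sequence and "GCAUAUAC" in fs.sequence
        # fragment order follows ascending author ranges
        first_fragment = "".join(seq[561:586])
        assert fs.sequence.startswith(first_fragment)
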