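"""Domain architecture: assignment, interaction matrices, boundary refinement.

A domain architecture is a list of :class:`DomainDefinition` ranges (inclusive
author-number ranges, e.g. the seven-domain model whose Domain 0 spans
562–586, 1251–1270, 1648–1678, 1990–2057 and 2611–2625).  The module

* assigns every nucleotide to exactly one domain,
* counts raw and scaled domain×domain interaction matrices — diagonal
  elements normalized by the domain's nucleotide count N_i, off-diagonal by
  the pair average (N_i+N_j)/2,
* refines boundaries by greedy hill-climbing against a priority-weighted
  inter-domain interaction objective (pairing > stacking > base-phosphate >
  base-sugar), never splitting a helix across domains,
* reports inter-helix "interlock" interactions within a named helix set, and
* exports a domain as a single foldable RNA sequence (fragments joined at
  strand termini, with optional helix substitutions) for 2D folding tools
  that only accept canonical pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contacts import ContactSet
from .helices import HelixPartition
from .model import StructureModel


class DefinitionError(ValueError):
    """Overlapping or malformed domain definitions."""


class IntegrityError(ValueError):
    """A contact references a nucleotide outside the assignment."""


@dataclass(frozen=True)
class DomainDefinition:
    label: str
    ranges: tuple             # inclusive (start, end) author-number ranges
    chain: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "ranges",
                           tuple((int(a), int(b)) for a, b in self.ranges))
        for a, b in self.ranges:
            if a > b:
                raise DefinitionError(f"domain {self.label}: bad range {a}-{b}")

    def contains(self, ref) -> bool:
        chain, num = ref
        if self.chain is not None and chain != self.chain:
            return False
        return any(a <= num <= b for a, b in self.ranges)

    @property
    def size(self) -> int:
        return sum(b - a + 1 for a, b in self.ranges)


@dataclass
class DomainModel:
    name: str
    definitions: list
    assignment: dict          # ref -> label
    unassigned: list = field(default_factory=list)

    @property
    def labels(self) -> list:
        return [d.label for d in self.definitions]

    @property
    def n_per_domain(self) -> dict:
        counts = {d.label: 0 for d in self.definitions}
        for label in self.assignment.values():
            counts[label] += 1
        return counts


def check_definitions(definitions: Sequence[DomainDefinition]) -> None:
    """Raise if any two definitions claim an overlapping author-number range."""
    for d1, d2 in itertools.combinations(definitions, 2):
        if (d1.chain is not None and d2.chain is not None
                and d1.chain != d2.chain):
            continue
        for a1, b1 in d1.ranges:
            for a2, b2 in d2.ranges:
                if a1 <= b2 and a2 <= b1:
                    raise DefinitionError(
                        f"domains {d1.label} and {d2.label} overlap on "
                        f"{max(a1, a2)}-{min(b1, b2)}")


def assign_domains(model: StructureModel,
                   definitions: Sequence[DomainDefinition],
                   name: str = "custom") -> DomainModel:
    """Assign every nucleotide of the model to a domain; gaps are reported in
    ``unassigned`` rather than silently dropped."""
    definitions = list(definitions)
    check_definitions(definitions)
    assignment, unassigned = {}, []
    for nt in model.nucleotides:
        hit = [d.label for d in definitions if d.contains(nt.ref)]
        if hit:
            assignment[nt.ref] = hit[0]
        else:
            unassigned.append(nt.ref)
    return DomainModel(name, definitions, assignment, unassigned)


@dataclass
class ExclusionPolicy:
    """Which interaction classes count toward the domain matrices.

    The default mirrors "local secondary interactions excluded": helix-member
    base pairs are dropped, stacking is not counted at all (the matrix sums
    base-base, backbone-mediated and Mg-mediated interactions); when stacking
    is enabled, sequence-neighbour stacks are dropped.
    """

    secondary_pair_keys: frozenset = frozenset()
    include_stacking: bool = False
    exclude_adjacent_stacks: bool = True
    include_mg: bool = True


@dataclass
class InteractionMatrix:
    labels: list
    raw: np.ndarray           # symmetric integer counts
    scaled: np.ndarray
    n_per_domain: dict
    excluded: dict = field(default_factory=dict)

    def to_frame(self, which: str = "scaled") -> pd.DataFrame:
        data = self.scaled if which == "scaled" else self.raw
        return pd.DataFrame(data, index=self.labels, columns=self.labels)

    @property
    def trace_raw(self) -> int:
        return int(np.trace(self.raw))


def scale_matrix(raw: np.ndarray, sizes: Sequence[int]) -> np.ndarray:
    """Diagonal / N_i; off-diagonal / ((N_i+N_j)/2)."""
    n = np.asarray(sizes, dtype=float)
    d = len(n)
    scaled = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            denom = n[i] if i == j else (n[i] + n[j]) / 2.0
            scaled[i, j] = raw[i, j] / denom if denom > 0 else 0.0
    return scaled


def interaction_matrix(domain_model: DomainModel, contacts: ContactSet,
                       policy: Optional[ExclusionPolicy] = None) -> InteractionMatrix:
    """Raw and scaled domain×domain interaction counts.

    Counts base pairs (minus the policy's secondary set), base-phosphate and
    base-sugar contacts, and Mg bridges — a bridge with k partner residues
    contributes all C(k,2) partner pairs.  Every referenced nucleotide must be
    assigned.
    """
    policy = policy or ExclusionPolicy()
    labels = domain_model.labels
    index = {lab: k for k, lab in enumerate(labels)}
    d = len(labels)
    raw = np.zeros((d, d), dtype=int)
    assignment = domain_model.assignment

    def dom(ref):
        try:
            return index[assignment[ref]]
        except KeyError:
            raise IntegrityError(f"nucleotide {ref} is not assigned to a domain")

    def add(ref_a, ref_b):
        i, j = dom(ref_a), dom(ref_b)
        raw[i, j] += 1
        if i != j:
            raw[j, i] += 1

    n_excluded = {"secondary_pairs": 0, "adjacent_stacks": 0, "stacking": 0}
    for p in contacts.base_pairs:
        if p.key in policy.secondary_pair_keys:
            n_excluded["secondary_pairs"] += 1
            continue
        add(p.nt_i, p.nt_j)
    if policy.include_stacking:
        for s in contacts.stacks:
            adjacent = (s.nt_i[0] == s.nt_j[0]
                        and abs(s.nt_i[1] - s.nt_j[1]) == 1)
            if policy.exclude_adjacent_stacks and adjacent:
                n_excluded["adjacent_stacks"] += 1
                continue
            add(s.nt_i, s.nt_j)
    else:
        n_excluded["stacking"] = len(contacts.stacks)
    for c in contacts.base_phosphate:
        add(c.donor, c.acceptor)
    for c in contacts.base_sugar:
        add(c.donor, c.acceptor)
    if policy.include_mg:
        for b in contacts.mg_bridges:
            for ra, rb in itertools.combinations(b.partners, 2):
                add(ra, rb)

    sizes = [domain_model.n_per_domain[lab] for lab in labels]
    return InteractionMatrix(labels, raw, scale_matrix(raw, sizes),
                             dict(zip(labels, sizes)), n_excluded)


#: refinement priority weights, highest for base pairing
DEFAULT_PRIORITY_WEIGHTS = {
    "pair": 8.0, "stack": 4.0, "base_phosphate": 2.0, "base_sugar": 1.0,
}


def _weighted_interdomain(contact_items, assignment) -> float:
    total = 0.0
    for w, ra, rb in contact_items:
        da, db = assignment.get(ra), assignment.get(rb)
        if da is not None and db is not None and da != db:
            total += w
    return total


def _contact_items(contacts: ContactSet, weights: dict,
                   secondary_keys: frozenset) -> list:
    items = []
    for p in contacts.base_pairs:
        if p.key in secondary_keys:
            continue
        items.append((weights["pair"], p.nt_i, p.nt_j))
    for s in contacts.stacks:
        items.append((weights["stack"], s.nt_i, s.nt_j))
    for c in contacts.base_phosphate:
        items.append((weights["base_phosphate"], c.donor, c.acceptor))
    for c in contacts.base_sugar:
        items.append((weights["base_sugar"], c.donor, c.acceptor))
    return items


def _boundary_moves(assignment: dict):
    """Candidate moves: the first/last nucleotide of each contiguous same-label
    run may adopt the label of the neighbouring run."""
    by_chain: dict[str, list] = {}
    for (chain, num), label in assignment.items():
        by_chain.setdefault(chain, []).append((num, label))
    moves = []
    for chain, items in sorted(by_chain.items()):
        items.sort()
        for k in range(len(items) - 1):
            (n1, l1), (n2, l2) = items[k], items[k + 1]
            if l1 != l2:
                moves.append(((chain, n1), l2))
                moves.append(((chain, n2), l1))
    return moves


def refine_boundaries(domain_model: DomainModel, contacts: ContactSet,
                      weights: Optional[dict] = None,
                      helix_partition: Optional[HelixPartition] = None,
                      max_iter: int = 10000) -> DomainModel:
    """Greedy boundary refinement minimizing weighted inter-domain interactions.

    At each step the single boundary-nucleotide move with the largest strict
    decrease of the objective is applied; moves that would split a helix's
    members across two domains are illegal; terminates at a local optimum.
    """
    weights = dict(DEFAULT_PRIORITY_WEIGHTS, **(weights or {}))
    secondary = (frozenset(helix_partition.secondary_pair_keys())
                 if helix_partition else frozenset())
    items = _contact_items(contacts, weights, secondary)
    assignment = dict(domain_model.assignment)

    helix_of = {}
    members_of = {}
    if helix_partition is not None:
        for h in helix_partition.helices:
            members_of[h.helix_id] = h.members
            for ref in h.members:
                helix_of[ref] = h.helix_id

    def splits_helix(ref, new_label) -> bool:
        hid = helix_of.get(ref)
        if hid is None:
            return False
        labels = {new_label if r == ref else assignment.get(r)
                  for r in members_of[hid]}
        labels.discard(None)
        return len(labels) > 1

    current = _weighted_interdomain(items, assignment)
    for _ in range(max_iter):
        best_gain, best_move = 0.0, None
        for ref, new_label in _boundary_moves(assignment):
            if splits_helix(ref, new_label):
                continue
            old_label = assignment[ref]
            assignment[ref] = new_label
            val = _weighted_interdomain(items, assignment)
            assignment[ref] = old_label
            gain = current - val
            if gain > best_gain + 1e-12:
                best_gain, best_move = gain, (ref, new_label)
        if best_move is None:
            break
        assignment[best_move[0]] = best_move[1]
        current -= best_gain

    return DomainModel(domain_model.name, domain_model.definitions, assignment,
                       list(domain_model.unassigned))


def domain0_interlock_report(partition: HelixPartition, contacts: ContactSet,
                             helix_names: Sequence[str]) -> pd.DataFrame:
    """Count interlocking interactions between the named helices.

    For every unordered pair of named helices: base pairs between their
    members (a helix's own secondary pairs are excluded by construction since
    a pair within one helix links only that helix), base-phosphate/base-sugar
    contacts, and Mg bridges touching both.  Returns a tidy DataFrame with one
    row per helix pair.
    """
    members = {}
    for name in helix_names:
        hit = [h for h in partition.helices if h.helix_id == name]
        if not hit:
            raise KeyError(f"no helix named {name!r} in the partition")
        members[name] = hit[0].members

    def owners(ref):
        return [n for n, mem in members.items() if ref in mem]

    rows = {tuple(sorted(pair)): {"base_pairs": 0, "base_backbone": 0, "mg": 0}
            for pair in itertools.combinations(helix_names, 2)}

    def tally(ref_a, ref_b, kind):
        for na in owners(ref_a):
            for nb in owners(ref_b):
                if na != nb:
                    rows[tuple(sorted((na, nb)))][kind] += 1

    for p in contacts.base_pairs:
        tally(p.nt_i, p.nt_j, "base_pairs")
    for c in contacts.base_phosphate:
        tally(c.donor, c.acceptor, "base_backbone")
    for c in contacts.base_sugar:
        tally(c.donor, c.acceptor, "base_backbone")
    for b in contacts.mg_bridges:
        touched = {n for r in b.partners for n in owners(r)}
        for na, nb in itertools.combinations(sorted(touched), 2):
            rows[(na, nb)]["mg"] += 1

    df = pd.DataFrame(
        [{"helix_i": a, "helix_j": b, **counts,
          "total": sum(counts.values())}
         for (a, b), counts in sorted(rows.items())])
    return df


@dataclass
class FoldableSequence:
    sequence: str
    linker_positions: list            # 0-based indices where fragments join
    substitutions: list               # ((start, end), replacement) as applied

    def to_fasta(self, name: str = "domain") -> str:
        return f">{name}\n{self.sequence}\n"


def export_foldable_sequence(model: StructureModel, domain: DomainDefinition,
                             substitutions: Optional[list] = None,
                             chain: Optional[str] = None) -> FoldableSequence:
    """Concatenate a domain's fragments (ascending range order) into one
    foldable RNA string, recording the junctions and any helix substitutions.

    ``substitutions``: list of ((start, end), replacement_sequence) replacing
    the residues of an author-number range by an explicit sequence (used to
    swap a non-canonical helix strand for a canonical duplex strand before
    thermodynamic folding; the replacement length may differ).
    """
    substitutions = substitutions or []
    for (a, b), _ in substitutions:
        if not any(lo <= a and b <= hi for lo, hi in domain.ranges):
            raise DefinitionError(
                f"substitution range {a}-{b} is not inside the domain")

    by_number = {}
    for nt in model.nucleotides:
        if chain is not None and nt.chain_id != chain:
            continue
        by_number[nt.author_number] = nt.base_type

    fragments = []
    for lo, hi in sorted(domain.ranges):
        frag = []
        num = lo
        while num <= hi:
            sub = next((s for s in substitutions if s[0][0] == num), None)
            if sub is not None:
                frag.append(sub[1].upper().replace("T", "U"))
                num = sub[0][1] + 1
                continue
            if num in by_number:
                frag.append(by_number[num])
            num += 1
        fragments.append("".join(frag))

    sequence = "".join(fragments)
    linkers, pos = [], 0
    for frag in fragments[:-1]:
        pos += len(frag)
        linkers.append(pos)
    return FoldableSequence(sequence, linkers, list(substitutions))


def load_domain_definitions(path) -> list:
    """Read a domain-definition CSV: columns label, ranges ("a-b;c-d"), and an
    optional chain column."""
    df = pd.read_csv(path, dtype=str)
    out = []
    for _, row in df.iterrows():
        ranges = []
        for part in str(row["ranges"]).split(";"):
            a, b = part.strip().split("-")
            ranges.append((int(a), int(b)))
        chain = row.get("chain")
        if isinstance(chain, float) or chain in (None, "", "nan"):
            chain = None
        out.append(DomainDefinition(str(row["label"]), tuple(ranges), chain))
    return out


def load_helix_table(path) -> list:
    """Read a helix-naming CSV (helix_name, ranges "a-b;c-d") into the
    reference-table form used by :func:`ribodomain.helices.name_helices`."""
    df = pd.read_csv(path, dtype=str)
    out = []
    for _, row in df.iterrows():
        segments = []
        for part in str(row["ranges"]).split(";"):
            a, b = part.strip().split("-")
            segments.append((int(a), int(b)))
        out.append((str(row["helix_name"]), segments))
    return out
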