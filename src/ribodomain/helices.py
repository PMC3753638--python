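"""Partition paired nucleotides into helices; classify pairs secondary/tertiary.

A helix is a run of contiguously stacked base pairs in which every nucleotide
belongs to exactly one helix.  Two pairs are *contiguous* when at least one
strand side carries a stacking contact between the respective partners and the
other side is either stacked too or sequence-close (a bulge of up to
``bulge_max`` extruded nucleotides).  The resulting partition is polished by a
hill-climbing pass that reassigns boundary pairs whenever that raises the
total intra-helix stacking count, mirroring the optimality criterion
(maximal intra-helical, minimal inter-helical stacking) used to define the
revised rRNA helix inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .contacts import BasePair, StackingContact

DEFAULT_BULGE_MAX = 2
MIN_HELIX_PAIRS = 2


@dataclass
class Helix:
    helix_id: str
    pairs: list                      # ordered BasePair list
    members: set = field(default_factory=set)   # nucleotide refs, unique across partition

    @property
    def strand_segments(self) -> list:
        """Inclusive (chain, start, end) runs covering the member nucleotides."""
        by_chain: dict[str, list[int]] = {}
        for chain, num in sorted(self.members):
            by_chain.setdefault(chain, []).append(num)
        segments = []
        for chain, nums in sorted(by_chain.items()):
            start = prev = nums[0]
            for n in nums[1:]:
                if n > prev + 1:
                    segments.append((chain, start, prev))
                    start = n
                prev = n
            segments.append((chain, start, prev))
        return segments


@dataclass
class HelixPartition:
    helices: list
    unassigned_paired: list          # pairs not in any helix (lone pairs, demoted triples)
    stats: dict = field(default_factory=dict)

    def helix_of(self, ref) -> Optional[str]:
        for h in self.helices:
            if ref in h.members:
                return h.helix_id
        return None

    def secondary_pair_keys(self) -> set:
        return {p.key for h in self.helices for p in h.pairs}


@dataclass(frozen=True)
class PairStratum:
    pair_key: tuple
    stratum: str                     # "secondary" | "tertiary"
    helix_id: Optional[str] = None


def _pair_sort_key(p: BasePair):
    return (p.nt_i, p.nt_j)


def _seq_close(a, b, bulge_max: int) -> bool:
    return a[0] == b[0] and 0 < abs(a[1] - b[1]) <= bulge_max + 1


def _adjacent(p: BasePair, q: BasePair, stacked, bulge_max: int) -> bool:
    """Contiguity between two pairs: for one of the two strand alignments,
    one side stacked and the other side stacked or sequence-close."""
    for (a, b), (c, d) in (((p.nt_i, p.nt_j), (q.nt_i, q.nt_j)),
                           ((p.nt_i, p.nt_j), (q.nt_j, q.nt_i))):
        s1 = frozenset((a, c)) in stacked
        s2 = frozenset((b, d)) in stacked
        if (s1 and (s2 or _seq_close(b, d, bulge_max))) or \
           (s2 and (s1 or _seq_close(a, c, bulge_max))):
            return True
    return False


def _resolve_multipairs(pairs: list) -> tuple[list, list]:
    """Enforce unique pairing per nucleotide: in a base triple keep the pair
    with more hydrogen bonds (ties by mean distance then ref order); demote
    the rest."""
    keep, demoted = [], []
    strength = lambda p: (p.hbond_count, -p.hbond_mean_dist)
    taken: dict = {}
    for p in sorted(pairs, key=lambda p: (-p.hbond_count, p.hbond_mean_dist,
                                          _pair_sort_key(p))):
        if taken.get(p.nt_i) is None and taken.get(p.nt_j) is None:
            taken[p.nt_i] = p
            taken[p.nt_j] = p
            keep.append(p)
        else:
            demoted.append(p)
    keep.sort(key=_pair_sort_key)
    demoted.sort(key=_pair_sort_key)
    return keep, demoted


def _intra_stack_count(helices: Iterable[set], stacks: list) -> int:
    count = 0
    for s in stacks:
        for members in helices:
            if s.nt_i in members and s.nt_j in members:
                count += 1
                break
    return count


def _helix_members(pairs: list, bulge_max: int) -> set:
    """Pair partners plus extruded nucleotides interior to a strand segment."""
    members = set()
    for p in pairs:
        members.add(p.nt_i)
        members.add(p.nt_j)
    by_chain: dict[str, list[int]] = {}
    for chain, num in members:
        by_chain.setdefault(chain, []).append(num)
    for chain, nums in by_chain.items():
        nums.sort()
        for a, b in zip(nums, nums[1:]):
            if 1 < b - a <= bulge_max + 1:
                members.update((chain, k) for k in range(a + 1, b))
    return members


def partition_helices(pairs: list, stacks: list,
                      bulge_max: int = DEFAULT_BULGE_MAX,
                      min_pairs: int = MIN_HELIX_PAIRS) -> HelixPartition:
    """Group base pairs into helices by stacking contiguity.

    Deterministic given any input order: pairs and stacks are canonically
    sorted first.  Base triples are resolved before chaining; the partition is
    then locally optimized by boundary-pair reassignment against the
    intra-helix stacking objective.
    """
    pairs = sorted(pairs, key=_pair_sort_key)
    stacked = {frozenset((s.nt_i, s.nt_j)) for s in stacks}
    uniq, demoted = _resolve_multipairs(pairs)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(uniq)))
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            if _adjacent(uniq[i], uniq[j], stacked, bulge_max):
                graph.add_edge(i, j)

    groups = [sorted(c) for c in nx.connected_components(graph)]
    groups.sort(key=lambda c: _pair_sort_key(uniq[c[0]]))

    helix_pairlists: list[list] = []
    unassigned = list(demoted)
    for comp in groups:
        plist = [uniq[i] for i in comp]
        if len(plist) >= min_pairs:
            helix_pairlists.append(plist)
        else:
            unassigned.extend(plist)

    helix_pairlists = _hill_climb(helix_pairlists, stacks, stacked, bulge_max)

    helices = []
    for k, plist in enumerate(helix_pairlists):
        plist.sort(key=_pair_sort_key)
        helices.append(Helix(
            helix_id=f"HX{k + 1:03d}",
            pairs=plist,
            members=_helix_members(plist, bulge_max),
        ))
    member_sets = [h.members for h in helices]
    intra = _intra_stack_count(member_sets, stacks)
    stats = {"intra_helix_stacks": intra,
             "inter_helix_stacks": sum(
                 1 for s in stacks
                 if _in_different_helices(s, member_sets))}
    unassigned.sort(key=_pair_sort_key)
    return HelixPartition(helices, unassigned, stats)


def _in_different_helices(s: StackingContact, member_sets: list) -> bool:
    hi = hj = None
    for k, members in enumerate(member_sets):
        if s.nt_i in members:
            hi = k
        if s.nt_j in members:
            hj = k
    return hi is not None and hj is not None and hi != hj


def _hill_climb(pairlists: list, stacks, stacked, bulge_max: int) -> list:
    """Greedy boundary-pair reassignment maximizing intra-helix stacking."""

    def objective(pls):
        return _intra_stack_count([_helix_members(pl, bulge_max) for pl in pls],
                                  stacks)

    current = [list(pl) for pl in pairlists]
    best = objective(current)
    improved = True
    while improved:
        improved = False
        for src in range(len(current)):
            if len(current[src]) <= MIN_HELIX_PAIRS:
                continue
            for pos in (0, len(current[src]) - 1):
                pair = current[src][pos]
                for dst in range(len(current)):
                    if dst == src:
                        continue
                    if not any(_adjacent(pair, q, stacked, bulge_max)
                               for q in current[dst]):
                        continue
                    trial = [list(pl) for pl in current]
                    trial[src].remove(pair)
                    trial[dst].append(pair)
                    val = objective(trial)
                    if val > best:
                        current, best, improved = trial, val, True
                        break
                if improved:
                    break
            if improved:
                break
    return current


class NamingConflictError(ValueError):
    """A helix overlaps two reference names at >= the naming threshold."""


def name_helices(partition: HelixPartition, reference_table: list,
                 threshold: float = 0.5) -> HelixPartition:
    """Rename helices from a reference table of named nucleotide ranges.

    ``reference_table``: iterable of (name, segments) where segments is a list
    of inclusive (start, end) author-number ranges.  A helix adopts a name
    when >= ``threshold`` of its members fall inside that name's ranges;
    unmatched helices keep sequential ids; unmatched reference entries are
    reported in ``partition.stats['unmatched_reference_names']``.
    """
    used = set()
    for h in partition.helices:
        candidates = []
        for name, segments in reference_table:
            inside = sum(
                1 for (_, num) in h.members
                if any(lo <= num <= hi for lo, hi in segments))
            frac = inside / len(h.members) if h.members else 0.0
            if frac >= threshold:
                candidates.append((name, frac))
        if len(candidates) > 1:
            candidates.sort(key=lambda c: -c[1])
            if abs(candidates[0][1] - candidates[1][1]) < 1e-12:
                raise NamingConflictError(
                    f"helix {h.helix_id} matches {[c[0] for c in candidates]}")
        if candidates:
            h.helix_id = max(candidates, key=lambda c: c[1])[0]
            used.add(h.helix_id)
    partition.stats["unmatched_reference_names"] = sorted(
        name for name, _ in reference_table if name not in used)
    return partition


class PairIntegrityError(ValueError):
    pass


def stratify_pairs(partition: HelixPartition, pairs: list) -> list:
    """Label every pair secondary (member pair of a helix) or tertiary."""
    secondary = {}
    for h in partition.helices:
        for p in h.pairs:
            secondary[p.key] = h.helix_id
    out = []
    for p in sorted(pairs, key=_pair_sort_key):
        if p.key in secondary:
            out.append(PairStratum(p.key, "secondary", secondary[p.key]))
        else:
            out.append(PairStratum(p.key, "tertiary"))
    return out


def reclassification_report(strata_a: list, strata_b: list) -> dict:
    """Pairs whose secondary/tertiary stratum differs between two inventories.

    Returns {"a_only_secondary": [...], "b_only_secondary": [...]} of pair keys
    — e.g. tertiary interactions of one architecture that a revised helix
    inventory converts to secondary.
    """
    sec_a = {s.pair_key for s in strata_a if s.stratum == "secondary"}
    sec_b = {s.pair_key for s in strata_b if s.stratum == "secondary"}
    return {
        "a_only_secondary": sorted(sec_a - sec_b),
        "b_only_secondary": sorted(sec_b - sec_a),
    }
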