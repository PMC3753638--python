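"""Per-column conservation of a 23S/28S rRNA multiple sequence alignment.

The conservation measure is the per-column Shannon entropy over the four
nucleotide types,

    H = − Σ_i p_i log₂ p_i ,   i ∈ {A, C, G, U},

with p_i the fractional occupancy of type i in the column.  H ranges from 0
(universally conserved position) to 2 bits (all four types equally common).
Paired columns are additionally classified into three conservation groups:
conserved identity + pairing geometry, conserved geometry only, and conserved
canonical complementarity (co-variation) without identity conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

NUCLEOTIDES = ("A", "C", "G", "U")
_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
              ("G", "U"), ("U", "G")}


class AlignmentFormatError(ValueError):
    pass


def read_alignment(path, fmt: str = "fasta"):
    """Read a FASTA or Stockholm alignment; sequences are upper-cased and
    T→U-normalized; equal row lengths are enforced."""
    if fmt not in ("fasta", "stockholm"):
        raise AlignmentFormatError(f"unsupported alignment format {fmt!r}")
    try:
        aln = AlignIO.read(path, fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path}: {exc}") from exc
    rows = [str(rec.seq).upper().replace("T", "U") for rec in aln]
    ids = [rec.id for rec in aln]
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise AlignmentFormatError(f"ragged alignment: row lengths {sorted(widths)}")
    return Alignment(ids, rows)


@dataclass
class Alignment:
    ids: list
    rows: list

    def __post_init__(self):
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise AlignmentFormatError(
                f"ragged alignment: row lengths {sorted(widths)}")
        self.rows = [r.upper().replace("T", "U") for r in self.rows]

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, index_1based: int) -> str:
        if not 1 <= index_1based <= self.width:
            raise IndexError(f"column {index_1based} out of range 1..{self.width}")
        return "".join(r[index_1based - 1] for r in self.rows)


def from_biopython(aln) -> Alignment:
    return Alignment([rec.id for rec in aln],
                     [str(rec.seq) for rec in aln])


@dataclass
class AlignmentColumnProfile:
    column_index: int                # 1-based
    p: dict                          # nucleotide -> fraction
    gap_fraction: float
    H: Optional[float]               # bits; None for an all-gap column
    flags: list = field(default_factory=list)


def shannon_entropy(p: Sequence[float]) -> float:
    """H in bits with the 0·log0 := 0 convention."""
    arr = np.asarray(p, dtype=float)
    nz = arr[arr > 0]
    return float(-(nz * np.log2(nz)).sum())


def column_profile(alignment: Alignment, column_index: int,
                   gap_policy: str = "exclude") -> AlignmentColumnProfile:
    """Nucleotide frequencies and entropy of one column.

    gap_policy "exclude": gaps/ambiguity codes are dropped and p renormalized
    over the four nucleotide types; "count": the denominator keeps all rows,
    so heavily gapped columns are biased toward 0 occupancy.  An all-gap
    column under "exclude" yields an undefined (None) entropy, flagged rather
    than silently reported as 0.
    """
    if gap_policy not in ("exclude", "count"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    col = alignment.column(column_index)
    counts = {nt: col.count(nt) for nt in NUCLEOTIDES}
    n_known = sum(counts.values())
    n_total = len(col)
    gap_fraction = 1.0 - n_known / n_total if n_total else 1.0
    flags = []
    if gap_fraction > 0.5:
        flags.append("low_coverage")
    denom = n_known if gap_policy == "exclude" else n_total
    if denom == 0 or (gap_policy == "exclude" and n_known == 0):
        return AlignmentColumnProfile(column_index,
                                      {nt: 0.0 for nt in NUCLEOTIDES},
                                      gap_fraction, None, flags + ["all_gap"])
    p = {nt: counts[nt] / denom for nt in NUCLEOTIDES}
    return AlignmentColumnProfile(column_index, p, gap_fraction,
                                  shannon_entropy(list(p.values())), flags)


def reference_numbering(alignment: Alignment, ref_id: str) -> dict:
    """Map alignment columns (1-based) to the reference row's ungapped
    positions (1-based); columns gapped in the reference map to None."""
    if ref_id not in alignment.ids:
        raise KeyError(f"reference row {ref_id!r} not in alignment")
    row = alignment.rows[alignment.ids.index(ref_id)]
    mapping, pos = {}, 0
    for col, ch in enumerate(row, start=1):
        if ch in NUCLEOTIDES:
            pos += 1
            mapping[col] = pos
        else:
            mapping[col] = None
    return mapping


def entropy_track(alignment: Alignment, gap_policy: str = "exclude",
                  ref_id: Optional[str] = None) -> pd.DataFrame:
    """Per-column profile table: position, p_A..p_U, gap_fraction, H (NaN when
    undefined) and, when a reference row is given, its ungapped numbering."""
    ref_map = reference_numbering(alignment, ref_id) if ref_id else None
    records = []
    for col in range(1, alignment.width + 1):
        prof = column_profile(alignment, col, gap_policy)
        rec = {"position": col,
               **{f"p_{nt}": prof.p[nt] for nt in NUCLEOTIDES},
               "gap_fraction": prof.gap_fraction,
               "H": np.nan if prof.H is None else prof.H,
               "flags": ";".join(prof.flags)}
        if ref_map is not None:
            rec["ref_number"] = ref_map[col]
        records.append(rec)
    return pd.DataFrame(records)


@dataclass(frozen=True)
class ConservationGroupLabel:
    columns: tuple                   # (col_i, col_j), 1-based
    group: Optional[int]             # 1, 2, 3 or None (unclassified)
    identity: tuple                  # max occupancy per column
    complementarity: float           # fraction of rows forming canonical pairs
    geometry_consistent: Optional[float]


def pair_complementarity(alignment: Alignment, col_i: int, col_j: int) -> float:
    """Fraction of rows whose (col_i, col_j) letters form a canonical pair,
    among rows unambiguous in both columns."""
    ci, cj = alignment.column(col_i), alignment.column(col_j)
    known = [(a, b) for a, b in zip(ci, cj)
             if a in NUCLEOTIDES and b in NUCLEOTIDES]
    if not known:
        return 0.0
    good = sum(1 for ab in known if ab in _CANONICAL)
    return good / len(known)


def classify_conservation_groups(alignment: Alignment, paired_columns: list,
                                 pair_annotations: Optional[dict] = None,
                                 identity_threshold: float = 0.9,
                                 complementarity_threshold: float = 0.9,
                                 geometry_threshold: float = 0.9) -> list:
    """Classify paired columns into the three conservation groups.

    * group 1 — base identity conserved in both columns (max occupancy >=
      identity threshold) and the annotated pairing geometry consistent;
    * group 2 — geometry consistent, identity below threshold;
    * group 3 — canonical complementarity (co-variation) above threshold
      without identity conservation.

    ``pair_annotations`` maps (col_i, col_j) to a geometry-consistency
    fraction in [0, 1] (e.g. the fraction of homologs keeping the annotated
    Leontis–Westhof class); absent annotations mean geometry unknown.
    """
    pair_annotations = pair_annotations or {}
    out = []
    for col_i, col_j in paired_columns:
        prof_i = column_profile(alignment, col_i)
        prof_j = column_profile(alignment, col_j)
        if prof_i.H is None or prof_j.H is None:
            raise ValueError(f"columns {col_i},{col_j}: all-gap column supplied")
        id_i = max(prof_i.p.values())
        id_j = max(prof_j.p.values())
        geom = pair_annotations.get((col_i, col_j))
        comp = pair_complementarity(alignment, col_i, col_j)
        identity_ok = min(id_i, id_j) >= identity_threshold
        geometry_ok = geom is not None and geom >= geometry_threshold
        if identity_ok and geometry_ok:
            group = 1
        elif geometry_ok:
            group = 2
        elif comp >= complementarity_threshold and not identity_ok:
            group = 3
        else:
            group = None
        out.append(ConservationGroupLabel((col_i, col_j), group,
                                          (id_i, id_j), comp, geom))
    return out
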