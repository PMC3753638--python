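"""Reading and writing macromolecular structures (mmCIF / PDB) via gemmi.

Only RNA residues and free ions are exposed; proteins, waters and DNA are
dropped at read time.  Author numbering and insertion codes are preserved.
Multi-model files use model 1 only (a warning is logged).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import gemmi
import numpy as np

from .model import (
    ALLOWED_IONS,
    MODIFIED_BASE_PARENTS,
    STANDARD_BASES,
    Atom,
    IonRecord,
    NucleotideRecord,
    StructureModel,
)

logger = logging.getLogger(__name__)

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
_DNA = {"DA", "DC", "DG", "DT", "DU", "DI"}
_SOLVENT = {"HOH", "WAT", "DOD"}


class FormatError(ValueError):
    """File could not be parsed under the requested dialect."""


class EmptySelectionError(ValueError):
    """The selection contains no RNA residues."""


def _classify_residue(res: gemmi.Residue) -> str | None:
    """Return parent base letter for an RNA residue, else None."""
    name = res.name.strip().upper()
    if name in _AMINO_ACIDS or name in _DNA or name in _SOLVENT:
        return None
    if name in STANDARD_BASES:
        return name
    if name in MODIFIED_BASE_PARENTS:
        return MODIFIED_BASE_PARENTS[name]
    # unknown residue: accept as RNA only if it has a ribose with 2'-OH and a
    # glycosidic nitrogen; parent base then guessed from ring atoms
    names = {a.name for a in res}
    if "C1'" in names and "O2'" in names and ("N9" in names or "N1" in names):
        if "N9" in names:
            return "G" if "O6" in names else "A"
        return "U" if "O4" in names else "C"
    return None


def _dedupe_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, tie -> first seen."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve original atom order
    seen = set()
    out = []
    for atom in res:
        if atom.name in seen:
            continue
        seen.add(atom.name)
        out.append(best[atom.name])
    return out


def read_structure(path, fmt: str = "auto") -> StructureModel:
    """Read a structure file and return its RNA residues and ions (model 1).

    Parameters
    ----------
    path : str or Path
        Input file (mmCIF or PDB).
    fmt : {"auto", "mmcif", "pdb"}
        Dialect; "auto" dispatches on file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "auto":
            st = gemmi.read_structure(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        elif fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise FormatError(f"{path}: no coordinate model")
    if len(st) > 1:
        logger.warning("%s: %d models present, using model 1 only", path, len(st))
    st.setup_entities()
    mdl = st[0]

    nucleotides: list[NucleotideRecord] = []
    ions: list[IonRecord] = []
    for chain in mdl:
        for res in chain:
            rname = res.name.strip().upper()
            if rname in ALLOWED_IONS and len(res) == 1:
                a = res[0]
                ions.append(IonRecord(
                    element=rname,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    id=f"{chain.name}:{rname}{res.seqid.num}",
                ))
                continue
            base = _classify_residue(res)
            if base is None:
                continue
            atoms = [
                Atom(a.name, (a.element.name or "X").upper(),
                     np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in _dedupe_altloc(res)
                if a.element.name.upper() != "H"
            ]
            if not atoms:
                continue
            nucleotides.append(NucleotideRecord(
                chain_id=chain.name,
                author_number=res.seqid.num,
                base_type=base,
                atoms=atoms,
                insertion_code=(res.seqid.icode or "").strip(),
                mod_code=rname if rname not in STANDARD_BASES else None,
            ))

    if not nucleotides:
        raise EmptySelectionError(f"{path}: no RNA residues found")
    return StructureModel(nucleotides, ions, source=f"{path.name} model 1")


def select_chain(model: StructureModel, chain_id: str) -> StructureModel:
    """Restrict nucleotides to one chain; ions are retained (they are assigned
    to contacts by distance, not to chains)."""
    if chain_id not in model.chains:
        raise KeyError(f"chain {chain_id!r} not present (have {model.chains})")
    nts = [nt for nt in model.nucleotides if nt.chain_id == chain_id]
    return StructureModel(nts, list(model.ions),
                          source=f"{model.source} chain {chain_id}")


def to_gemmi(model: StructureModel, name: str = "ribodomain") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    mdl = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def chain(cid: str) -> gemmi.Chain:
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        return chains[cid]

    for nt in model.nucleotides:
        res = gemmi.Residue()
        res.name = nt.mod_code or nt.base_type
        res.seqid = gemmi.SeqId(nt.author_number, nt.insertion_code or " ")
        for a in nt.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element.capitalize())
            ga.pos = gemmi.Position(*a.coord)
            ga.occ = 1.0
            res.add_atom(ga)
        chain(nt.chain_id).add_residue(res)
    for k, ion in enumerate(model.ions, start=1):
        res = gemmi.Residue()
        res.name = ion.element
        res.seqid = gemmi.SeqId(k, " ")
        res.het_flag = "H"
        ga = gemmi.Atom()
        ga.name = ion.element
        ga.element = gemmi.Element(ion.element.capitalize())
        ga.pos = gemmi.Position(*ion.coord)
        ga.occ = 1.0
        res.add_atom(ga)
        chain("Z").add_residue(res)
    for ch in chains.values():
        mdl.add_chain(ch)
    st.add_model(mdl)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path, fmt: str = "auto") -> None:
    """Write the model as mmCIF or PDB (dialect from extension when "auto")."""
    path = Path(path)
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = to_gemmi(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "mmcif":
            st.make_mmcif_document().write_file(str(path))
        elif fmt == "pdb":
            st.write_pdb(str(path))
        else:
            raise ValueError(f"unknown format {fmt!r}")
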