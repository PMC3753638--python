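"""End-to-end orchestration: contacts → helices → domains → shapes → report.

``run_pipeline`` composes the whole analysis for one structure under one or
two domain architectures (e.g. the traditional six-domain model vs the
seven-domain revision with a central core domain) and produces:

* a per-nucleotide annotation table (domain labels per architecture, helix id,
  pairing partners and class, secondary/tertiary stratum, optional alignment
  entropy and distance from the peptidyl transfer center),
* raw and scaled interaction matrices per architecture,
* per-domain shape metrics per architecture,
* an architecture comparison (matrix traces, mean sphericities, reclassified
  pairs) and a manifest with every threshold used.

Everything is deterministic given the inputs and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import contacts as contacts_mod
from .contacts import ContactSet, DetectionParams, detect_all
from .conservation import Alignment, entropy_track
from .domains import (DomainModel, ExclusionPolicy, InteractionMatrix,
                      assign_domains, interaction_matrix)
from .helices import (HelixPartition, name_helices, partition_helices,
                      reclassification_report, stratify_pairs)
from .model import StructureModel
from .shape import domain_shape_report, ptc_distance_map


@dataclass
class ArchitectureComparison:
    names: tuple
    trace_raw: dict                 # architecture -> total intra-domain count
    total_raw: dict                 # architecture -> total interaction count
    mean_sphericity: dict
    n_per_domain: dict
    reclassified: dict              # from reclassification_report


@dataclass
class PipelineResult:
    annotation: pd.DataFrame
    contacts: ContactSet
    partition: HelixPartition
    domain_models: dict             # name -> DomainModel
    matrices: dict                  # name -> InteractionMatrix
    shapes: dict                    # name -> (per-domain metrics, mean)
    comparison: Optional[ArchitectureComparison]
    manifest: dict


def _annotation_table(model: StructureModel, partition: HelixPartition,
                      strata: dict, domain_models: dict,
                      entropy: Optional[pd.DataFrame],
                      onion) -> pd.DataFrame:
    pair_partner: dict = {}
    pair_class: dict = {}
    for p in strata["pairs"]:
        pair_partner.setdefault(p.nt_i, []).append(p.nt_j)
        pair_partner.setdefault(p.nt_j, []).append(p.nt_i)
        pair_class.setdefault(p.nt_i, []).append(p.lw_class)
        pair_class.setdefault(p.nt_j, []).append(p.lw_class)
    stratum_of = {}
    for s in strata.get("strata", []):
        for ref in s.pair_key:
            stratum_of.setdefault(ref, s.stratum)

    h_by_ref = {}
    for h in partition.helices:
        for ref in h.members:
            h_by_ref[ref] = h.helix_id

    ent_by_number = {}
    if entropy is not None and "ref_number" in entropy.columns:
        for _, row in entropy.iterrows():
            if row["ref_number"] is not None and not pd.isna(row["ref_number"]):
                ent_by_number[int(row["ref_number"])] = row["H"]

    records = []
    for nt in model.nucleotides:
        rec = {
            "chain": nt.chain_id,
            "author_number": nt.author_number,
            "base": nt.base_type,
            "modified": nt.mod_code or "",
            "helix_id": h_by_ref.get(nt.ref, ""),
            "pair_partners": ";".join(
                f"{c}:{n}" for c, n in pair_partner.get(nt.ref, [])),
            "pair_class": ";".join(pair_class.get(nt.ref, [])),
            "stratum": stratum_of.get(nt.ref, ""),
        }
        for name, dm in domain_models.items():
            rec[f"domain_{name}"] = dm.assignment.get(nt.ref, "")
        rec["H"] = ent_by_number.get(nt.author_number, np.nan)
        rec["ptc_distance"] = (onion.distances[nt.ref]
                               if onion is not None else np.nan)
        records.append(rec)
    return pd.DataFrame(records)


def run_pipeline(model: StructureModel,
                 domain_definitions: dict,
                 helix_tables: Optional[dict] = None,
                 alignment: Optional[Alignment] = None,
                 alignment_ref_id: Optional[str] = None,
                 ptc_reference=None,
                 params: DetectionParams = DetectionParams(),
                 compute_shapes: bool = True,
                 shape_grid: float = 1.0,
                 shape_probe: float = 1.5) -> PipelineResult:
    """Run the full analysis.

    ``domain_definitions``: {architecture_name: [DomainDefinition, ...]} — one
    or two architectures.  ``helix_tables``: optional
    {architecture_name: reference helix-name table}; the first architecture's
    table also names the detected helices in the annotation.
    """
    cset = detect_all(model, params)
    partition = partition_helices(cset.base_pairs, cset.stacks)
    helix_tables = helix_tables or {}
    arch_names = list(domain_definitions)
    if arch_names and arch_names[0] in helix_tables:
        partition = name_helices(partition, helix_tables[arch_names[0]])

    strata_by_arch = {}
    domain_models = {}
    matrices = {}
    shapes = {}
    for name, defs in domain_definitions.items():
        dm = assign_domains(model, defs, name=name)
        domain_models[name] = dm
        strata_by_arch[name] = stratify_pairs(partition, cset.base_pairs)
        policy = ExclusionPolicy(
            secondary_pair_keys=frozenset(partition.secondary_pair_keys()))
        matrices[name] = interaction_matrix(dm, cset, policy)
        if compute_shapes:
            shapes[name] = domain_shape_report(model, dm, shape_probe, shape_grid)

    entropy = None
    if alignment is not None:
        entropy = entropy_track(alignment, ref_id=alignment_ref_id)
    onion = ptc_distance_map(model, ptc_reference) if ptc_reference is not None else None

    comparison = None
    if len(arch_names) >= 2:
        a, b = arch_names[0], arch_names[1]
        comparison = ArchitectureComparison(
            names=(a, b),
            trace_raw={n: matrices[n].trace_raw for n in (a, b)},
            total_raw={n: int(matrices[n].raw.sum()
                              - np.trace(matrices[n].raw)) // 2
                          + matrices[n].trace_raw
                       for n in (a, b)},
            mean_sphericity={n: shapes[n][1] for n in (a, b)} if shapes else {},
            n_per_domain={n: domain_models[n].n_per_domain for n in (a, b)},
            reclassified=reclassification_report(strata_by_arch[a],
                                                 strata_by_arch[b]),
        )

    annotation = _annotation_table(
        model, partition,
        {"pairs": cset.base_pairs,
         "strata": strata_by_arch[arch_names[0]] if arch_names else []},
        domain_models, entropy, onion)

    manifest = {
        "source": model.source,
        "n_nucleotides": len(model),
        "n_ions": len(model.ions),
        "detection_params": cset.params_dict(),
        "architectures": {n: [(d.label, list(d.ranges)) for d in defs]
                          for n, defs in domain_definitions.items()},
        "shape": {"grid_spacing": shape_grid, "probe_radius": shape_probe}
                 if compute_shapes else None,
        "versions": {"ribodomain": _version()},
    }
    return PipelineResult(annotation, cset, partition, domain_models,
                          matrices, shapes, comparison, manifest)


def _version() -> str:
    from . import __version__
    return __version__


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write annotation.csv, matrix_<arch>_{raw,scaled}.csv, shape_<arch>.csv,
    comparison.json and manifest.json."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.annotation.to_csv(outdir / "annotation.csv", index=False)
    for name, mat in result.matrices.items():
        mat.to_frame("raw").to_csv(outdir / f"matrix_{name}_raw.csv")
        mat.to_frame("scaled").to_csv(outdir / f"matrix_{name}_scaled.csv")
    for name, (per_domain, mean) in result.shapes.items():
        rows = [{"domain": lab, "volume": m.volume, "surface_area": m.surface_area,
                 "sphericity": m.sphericity} for lab, m in per_domain.items()]
        rows.append({"domain": "mean", "volume": np.nan, "surface_area": np.nan,
                     "sphericity": mean})
        pd.DataFrame(rows).to_csv(outdir / f"shape_{name}.csv", index=False)
    if result.comparison is not None:
        comp = result.comparison
        payload = {
            "architectures": list(comp.names),
            "trace_raw": comp.trace_raw,
            "total_raw": comp.total_raw,
            "mean_sphericity": comp.mean_sphericity,
            "n_per_domain": comp.n_per_domain,
            "reclassified": {k: [list(map(list, pair)) for pair in v]
                             for k, v in comp.reclassified.items()},
        }
        (outdir / "comparison.json").write_text(json.dumps(payload, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
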