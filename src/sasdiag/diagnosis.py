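"""Effect diagnosis: flag assembly, the decision tree, cross-structure
aggregation, and the end-to-end pipeline.

The decision tree evaluates one variant's flag vector column by column,
left to right — active site, then interface, then buried, then sequence
propensity (aggregation or switch) — with the ddG tier choosing between a
firm "Disrupt ..." and a tentative "Potential disruption ..." label; a
variant with no flag at all and no high ddG is "Likely non pathogenic
mutation". A destabilising variant (high ddG) carrying no positional flag
is labelled a folding disruptor: strong destabilisation prevents folding
wherever the residue sits.

A variant seen in several crystal forms is aggregated by OR-ing the
boolean flags (a label earned in any one crystal is kept) and taking the
most destabilising ddG, with per-flag provenance retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from . import residue_annotation, sequence_scores, stability, structure_io, tables
from .errors import SasdiagError
from .model import SeqMap, Structure, StructureMeta, Variant
from .residue_annotation import Pocket, ResidueAnnotation

__all__ = [
    "AnnotationFlags",
    "DiagnosticLabel",
    "LABELS",
    "CATEGORIES",
    "build_flags",
    "diagnose",
    "aggregate_structures",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]


@dataclass(frozen=True)
class AnnotationFlags:
    """The boolean vector plus ddG consumed by the decision tree."""

    ddg: Optional[float]
    ddg_high: bool
    active_site: bool
    interface: bool
    buried: bool
    high_aggregability: bool
    high_switchability: bool
    structure_id: str = ""
    #: per-flag provenance after aggregation: flag name -> structure ids
    provenance: tuple[tuple[str, tuple[str, ...]], ...] = ()


@dataclass(frozen=True)
class DiagnosticLabel:
    label: str
    category: str
    fired_rule: int  # 1-9


_FUNCTION, _INTERFACE, _FOLDING, _STRUCTURE = (
    "protein function", "protein interface", "protein folding", "protein structure",
)
NON_PATHOGENIC = "Likely non pathogenic mutation"

LABELS = tuple(
    [f"Disrupt {k}" for k in (_FUNCTION, _INTERFACE, _FOLDING, _STRUCTURE)]
    + [f"Potential disruption {k}" for k in (_FUNCTION, _INTERFACE, _FOLDING, _STRUCTURE)]
    + [NON_PATHOGENIC]
)

#: Effect-category mapping; the non-pathogenic label is the only one with
#: category "None".
CATEGORIES = {
    _FUNCTION: "Active site + Binding",
    _INTERFACE: "Protein-protein interaction",
    _FOLDING: "Folding",
    _STRUCTURE: "Folding",
}


def diagnose(flags: AnnotationFlags) -> DiagnosticLabel:
    """Apply the decision tree to one flag vector.

    Total over the whole flag space; exactly one of the nine rules fires.
    Unknown ddG has already been folded into ``ddg_high=False`` upstream.
    """
    if flags.active_site:
        kind, rule = _FUNCTION, 1
    elif flags.interface:
        kind, rule = _INTERFACE, 2
    elif flags.buried:
        kind, rule = _FOLDING, 3
    elif flags.high_aggregability or flags.high_switchability:
        kind, rule = _STRUCTURE, 4
    elif flags.ddg_high:
        # destabilisation alone: folding disruptor (see module docstring)
        kind, rule = _FOLDING, 3
    else:
        return DiagnosticLabel(NON_PATHOGENIC, "None", 9)
    if flags.ddg_high:
        return DiagnosticLabel(f"Disrupt {kind}", CATEGORIES[kind], rule)
    return DiagnosticLabel(f"Potential disruption {kind}", CATEGORIES[kind], rule + 4)


def build_flags(
    variant: Variant,
    annotation: ResidueAnnotation,
    structure_id: str,
    ddg: Optional[float] = None,
    high_aggregability: bool = False,
    high_switchability: bool = False,
    ddg_threshold: float = tables.DDG_THRESHOLD,
) -> AnnotationFlags:
    """Assemble one variant's flags on one structure.

    ``active_site`` is binding OR catalytic at the mapped residue; a
    residue is ``buried`` only when its exposure is defined and does not
    exceed the threshold — glycine (undefined exposure) is never buried.
    """
    return AnnotationFlags(
        ddg=ddg,
        ddg_high=stability.high_ddg(ddg, ddg_threshold) if ddg is not None else False,
        active_site=annotation.binding or annotation.catalytic,
        interface=annotation.interface,
        buried=annotation.exposed is False,
        high_aggregability=high_aggregability,
        high_switchability=high_switchability,
        structure_id=structure_id,
    )


_BOOL_FLAGS = (
    "active_site", "interface", "buried", "high_aggregability",
    "high_switchability", "ddg_high",
)


def aggregate_structures(
    per_structure: Sequence[AnnotationFlags],
    ddg_threshold: float = tables.DDG_THRESHOLD,
    ddg_reduce: str = "max",
) -> AnnotationFlags:
    """Combine one variant's flags across crystal forms.

    Boolean flags are OR-combined — a flag earned in any single structure
    is kept. ddG is reduced over the known values (default: maximum, the
    most destabilising; ``mean`` and ``min`` are available) and the high
    flag recomputed from the reduced value. Per-flag provenance records
    which structures contributed.
    """
    if not per_structure:
        raise ValueError("nothing to aggregate: empty flag list")
    ddgs = [f.ddg for f in per_structure if f.ddg is not None]
    if ddgs:
        if ddg_reduce == "max":
            ddg = max(ddgs)
        elif ddg_reduce == "min":
            ddg = min(ddgs)
        elif ddg_reduce == "mean":
            ddg = sum(ddgs) / len(ddgs)
        else:
            raise ValueError(f"unknown ddg_reduce {ddg_reduce!r}")
    else:
        ddg = None
    combined = {
        name: any(getattr(f, name) for f in per_structure) for name in _BOOL_FLAGS
    }
    combined["ddg_high"] = stability.high_ddg(ddg, ddg_threshold) if ddg is not None else False
    provenance = tuple(
        (name, tuple(f.structure_id for f in per_structure if getattr(f, name)))
        for name in _BOOL_FLAGS
        if combined[name]
    )
    return AnnotationFlags(
        ddg=ddg,
        structure_id="+".join(dict.fromkeys(f.structure_id for f in per_structure)),
        provenance=provenance,
        **combined,
    )


# --- pipeline ---------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    ``structures`` are PDB file paths; per-structure side inputs (pockets,
    ddG difference tables) are keyed by structure id (= file stem).
    Variants come from ``variant_table``/``variant_dialect`` or directly
    as ``variants``.
    """

    ref_seq: str
    structures: list[str | Path]
    variants: Optional[list[Variant]] = None
    variant_table: Optional[str | Path] = None
    variant_dialect: str = "simple_tsv"
    target_chain: Optional[str] = None
    pockets: dict[str, str | Path] = field(default_factory=dict)
    foldx: dict[str, str | Path] = field(default_factory=dict)
    catalytic_catalog: Optional[str | Path] = None
    did3: Optional[str | Path] = None
    msa: Optional[str | Path] = None
    agg_scores_wt: Optional[str | Path] = None
    switch_positions: Optional[str | Path] = None
    solvent_list: Optional[str | Path] = None
    min_coverage: int = tables.MIN_COVERAGE
    interface_cutoff: float = tables.INTERFACE_CUTOFF
    ligand_cutoff: float = tables.LIGAND_CONTACT_CUTOFF
    exposure_threshold: float = tables.EXPOSURE_THRESHOLD
    druggability_threshold: float = tables.DRUGGABILITY_THRESHOLD
    ddg_threshold: float = tables.DDG_THRESHOLD
    aggregation_delta: float = tables.AGGREGATION_DELTA
    switch_delta: float = tables.SWITCH_DELTA
    identity_floor: float = tables.IDENTITY_FLOOR
    ddg_reduce: str = "max"
    sasa_points: int = 960
    out_dir: Optional[str | Path] = None


@dataclass
class VariantReport:
    variant: Variant
    per_structure: dict[str, tuple[AnnotationFlags, DiagnosticLabel]]
    aggregated_flags: AnnotationFlags
    aggregated: DiagnosticLabel
    caveats: list[str]
    conservation_bits: Optional[float] = None
    score_source: str = "surrogate"


@dataclass
class PipelineResult:
    selected: list[StructureMeta]
    annotations: dict[str, dict]            # structure id -> residue annotations
    reports: dict[str, VariantReport]       # variant short form -> report
    unmapped: list[str]                     # variants outside every crystal
    parse_issues: list
    summary: dict[str, int]                 # category -> variant count

    def to_json(self) -> str:
        payload = {
            "structures": [
                {
                    "structure_id": m.structure_id,
                    "covered_range": list(m.covered_range),
                    "resolution": m.resolution,
                    "ligands": sorted(m.ligand_codes),
                    "partners": sorted(m.partner_chains),
                }
                for m in self.selected
            ],
            "variants": {
                short: {
                    "per_structure": {
                        sid: {"flags": _flags_dict(fl), "label": lab.label,
                              "fired_rule": lab.fired_rule}
                        for sid, (fl, lab) in sorted(rep.per_structure.items())
                    },
                    "aggregated": {
                        "flags": _flags_dict(rep.aggregated_flags),
                        "label": rep.aggregated.label,
                        "category": rep.aggregated.category,
                        "fired_rule": rep.aggregated.fired_rule,
                        "caveats": rep.caveats,
                    },
                    "conservation_bits": rep.conservation_bits,
                    "score_source": rep.score_source,
                }
                for short, rep in sorted(self.reports.items())
            },
            "unmapped": sorted(self.unmapped),
            "summary": dict(sorted(self.summary.items())),
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_json_scalar)


def _json_scalar(obj):
    """Degrade numpy scalars to plain Python numbers."""
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


def _flags_dict(fl: AnnotationFlags) -> dict:
    d = asdict(fl)
    d["provenance"] = {name: list(sids) for name, sids in fl.provenance}
    return d


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the whole pipeline: parse and select structures, map variants,
    annotate residues, build flags, diagnose per structure, aggregate, and
    (optionally) write deterministic reports to ``config.out_dir``."""
    solvent = (
        structure_io.load_solvent_list(config.solvent_list)
        if config.solvent_list
        else tables.DEFAULT_SOLVENT_CODES
    )

    # -- structures and sequence maps
    parsed: dict[str, tuple[Structure, SeqMap, str]] = {}
    metas: list[StructureMeta] = []
    for path in config.structures:
        struct = structure_io.read_structure(path, solvent_codes=solvent)
        chain, seqmap = _pick_chain(struct, config)
        parsed[struct.structure_id] = (struct, seqmap, chain)
        metas.append(structure_io.structure_meta(struct, chain, seqmap))
    selected = structure_io.select_structures(metas, config.min_coverage)
    selected_ids = [m.structure_id for m in selected]

    # -- variants
    parse_issues: list = []
    if config.variants is not None:
        variants = list(config.variants)
    elif config.variant_table is not None:
        table = structure_io.read_variant_table(config.variant_table, config.variant_dialect)
        variants = table.variants
        parse_issues = table.issues
    else:
        raise SasdiagError("config provides neither variants nor variant_table")

    # -- optional side inputs
    did3 = residue_annotation.read_did3(config.did3) if config.did3 else set()
    stab_records: dict[str, dict[tuple, float]] = {}
    for sid, path in config.foldx.items():
        recs = stability.parse_foldx_output(path, structure_id=sid)
        stab_records[sid] = {r.variant_key: r.ddg for r in recs}
    columns = colmap = None
    if config.msa:
        columns, colmap = sequence_scores.read_msa_columns(config.msa)
    switch_external = None
    if config.switch_positions:
        switch_external = _read_switch_positions(config.switch_positions)
    # the aggregation delta always needs wt and mutant profiles from the
    # same scorer, so the surrogate computes both; an external wild-type
    # score file is carried through as provenance and report content
    surrogate_wt = sequence_scores.aggregation_profile(config.ref_seq)
    score_source = "external_file" if config.agg_scores_wt else "surrogate"

    # -- per-structure annotation
    annotations: dict[str, dict] = {}
    for sid in selected_ids:
        struct, seqmap, chain = parsed[sid]
        pockets: list[Pocket] = []
        if sid in config.pockets:
            pockets = residue_annotation.read_pockets(
                config.pockets[sid], structure=struct, ligand_cutoff=config.ligand_cutoff
            )
        catalytic: set = set()
        if config.catalytic_catalog:
            catalytic, _missing = residue_annotation.catalytic_residues(
                config.catalytic_catalog, sid, struct
            )
        annotations[sid] = residue_annotation.annotate_structure(
            struct,
            pockets=pockets,
            catalytic=catalytic,
            did3=did3,
            interface_cutoff=config.interface_cutoff,
            ligand_cutoff=config.ligand_cutoff,
            exposure_threshold=config.exposure_threshold,
            druggability_threshold=config.druggability_threshold,
            sasa_points=config.sasa_points,
        )

    # -- per-variant diagnosis
    reports: dict[str, VariantReport] = {}
    unmapped: list[str] = []
    for variant in variants:
        agg_flag = _aggregability(variant, config, surrogate_wt)
        switch_flag = sequence_scores.high_switchability(
            config.ref_seq, variant,
            delta_threshold=config.switch_delta,
            external_positions=switch_external,
        ) if _in_seq(variant, config.ref_seq) else False

        per_structure: dict[str, tuple[AnnotationFlags, DiagnosticLabel]] = {}
        for sid in selected_ids:
            struct, seqmap, chain = parsed[sid]
            if variant.position not in seqmap:
                continue
            key = seqmap[variant.position]
            ann = annotations[sid].get(key)
            if ann is None:
                continue
            ddg = stab_records.get(sid, {}).get(variant.key, variant.ddg)
            flags = build_flags(
                variant, ann, sid, ddg=ddg,
                high_aggregability=agg_flag,
                high_switchability=switch_flag,
                ddg_threshold=config.ddg_threshold,
            )
            per_structure[sid] = (flags, diagnose(flags))

        if not per_structure:
            unmapped.append(variant.short())
            continue
        combined = aggregate_structures(
            [fl for fl, _ in per_structure.values()],
            ddg_threshold=config.ddg_threshold,
            ddg_reduce=config.ddg_reduce,
        )
        caveats = []
        if combined.ddg is None:
            caveats.append("stability-unknown")
        conservation = None
        if columns is not None and _in_seq(variant, config.ref_seq):
            conservation = sequence_scores.conservation_score(
                columns, colmap, variant.position, variant.wt_aa
            )
        reports[variant.short()] = VariantReport(
            variant=variant,
            per_structure=per_structure,
            aggregated_flags=combined,
            aggregated=diagnose(combined),
            caveats=caveats,
            conservation_bits=conservation,
            score_source=score_source,
        )

    summary: dict[str, int] = {}
    for rep in reports.values():
        summary[rep.aggregated.category] = summary.get(rep.aggregated.category, 0) + 1

    result = PipelineResult(
        selected=selected,
        annotations=annotations,
        reports=reports,
        unmapped=unmapped,
        parse_issues=parse_issues,
        summary=summary,
    )
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _in_seq(variant: Variant, ref_seq: str) -> bool:
    return (
        1 <= variant.position <= len(ref_seq)
        and ref_seq[variant.position - 1].upper() == variant.wt_aa
    )


def _aggregability(variant, config, surrogate_wt) -> bool:
    if not _in_seq(variant, config.ref_seq):
        return False
    mut_seq = (
        config.ref_seq[: variant.position - 1]
        + variant.mut_aa
        + config.ref_seq[variant.position:]
    )
    mut = sequence_scores.aggregation_profile(mut_seq)
    return sequence_scores.high_aggregability(
        surrogate_wt, mut, variant.position, config.aggregation_delta
    )


def _read_switch_positions(path) -> set[int]:
    profile = sequence_scores.read_score_file(path)
    return {p for p in range(1, len(profile) + 1) if profile.at(p) > 0}


def _pick_chain(struct: Structure, config: PipelineConfig):
    """Choose the target chain: the configured one, else the polymer chain
    mapping best onto the reference sequence."""
    if config.target_chain is not None:
        chain = struct.get_chain(config.target_chain)
        return chain.chain_id, structure_io.map_sequence_to_structure(
            config.ref_seq, chain, config.identity_floor
        )
    best = None
    for chain in struct.polymer_chains():
        try:
            seqmap = structure_io.map_sequence_to_structure(
                config.ref_seq, chain, config.identity_floor
            )
        except SasdiagError:
            continue
        score = (len(seqmap.ref_to_structure), seqmap.identity)
        if best is None or score > best[0]:
            best = (score, chain.chain_id, seqmap)
    if best is None:
        raise SasdiagError(
            f"{struct.structure_id}: no chain maps onto the reference sequence"
        )
    return best[1], best[2]


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, anns in sorted(result.annotations.items()):
        residue_annotation.write_annotation_tsv(anns, out / f"{sid}.annotation.tsv", sid)
    (out / "report.json").write_text(result.to_json() + "\n")
    with open(out / "summary.tsv", "w") as fh:
        fh.write("category\tvariants\n")
        for category, count in sorted(result.summary.items()):
            fh.write(f"{category}\t{count}\n")
        fh.write(f"unmapped\t{len(result.unmapped)}\n")
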