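"""Structure and variant input.

Parses PDB-format structures (via Biopython behind this module surface),
classifies het-groups into polymer/solvent/ligand, applies the structure
selection rules (minimum sequence coverage, coverage-then-resolution
ranking, duplicates kept only when ligands or protein partners differ),
maps reference-sequence positions onto author-numbered residues by global
pairwise alignment, and reads variant tables in three dialects.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.PDB import PDBParser

from . import tables
from .errors import (
    FileParseError,
    NoPolymerError,
    NoUsableStructuresError,
    SequenceMismatchError,
    SynonymousVariantError,
    VariantParseError,
)
from .model import Atom, Chain, Residue, SeqMap, Structure, StructureMeta, Variant

__all__ = [
    "classify_het_group",
    "read_structure",
    "select_structures",
    "map_sequence_to_structure",
    "parse_variant",
    "format_variant",
    "read_variant_table",
    "VariantTable",
    "ParseIssue",
    "load_solvent_list",
    "structure_meta",
]


def classify_het_group(
    het_code: str,
    solvent_codes: Iterable[str] = tables.DEFAULT_SOLVENT_CODES,
) -> str:
    """Classify a residue/het code as ``polymer``, ``solvent`` or ``ligand``.

    Standard amino acids are polymer; codes in the (configurable) solvent
    list are solvent; everything else — unknown codes included — defaults
    to ligand, so an unrecognised compound can still confer binding labels.
    """
    code = het_code.strip().upper()
    if not code:
        raise ValueError("empty het code")
    if code in tables.AA3_TO_AA1:
        return "polymer"
    if code in set(solvent_codes):
        return "solvent"
    return "ligand"


def load_solvent_list(path: str | Path) -> frozenset[str]:
    """Read a solvent-code list: one code per line, ``#`` comments allowed."""
    codes = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip().upper()
        if line:
            codes.add(line)
    return frozenset(codes)


def _element_of(bio_atom) -> str:
    elem = (bio_atom.element or "").strip().upper()
    if not elem:
        # fall back on the first alphabetic character of the atom name
        name = bio_atom.get_name().strip()
        elem = next((c for c in name if c.isalpha()), "C").upper()
    return elem


def read_structure(
    path: str | Path,
    target_chains: Optional[Iterable[str]] = None,
    solvent_codes: Iterable[str] = tables.DEFAULT_SOLVENT_CODES,
) -> Structure:
    """Parse a PDB-format file into a :class:`Structure`.

    Author residue numbering and insertion codes are preserved verbatim.
    Polymer residues populate the chains; solvent and ligand het-groups go
    to ``Structure.het_groups`` (their chain id is kept on the residue).
    ``target_chains`` restricts parsing to the named chains.

    Raises :class:`NoPolymerError` if no polymer residue survives.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_structure = parser.get_structure(path.stem, str(path))
    wanted = set(target_chains) if target_chains is not None else None

    chains: list[Chain] = []
    het_groups: list[Residue] = []
    model = next(iter(bio_structure))  # first model only
    for bio_chain in model:
        chain_id = bio_chain.id
        if wanted is not None and chain_id not in wanted:
            continue
        polymer: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, seq_num, icode = bio_res.id
            resname = bio_res.get_resname().strip().upper()
            kind = classify_het_group(resname, solvent_codes)
            atoms = [
                Atom(
                    name=a.get_name().strip(),
                    element=_element_of(a),
                    coords=tuple(float(x) for x in a.coord),
                    b_factor=max(float(a.get_bfactor()), 0.0),
                )
                for a in bio_res
            ]
            if kind == "polymer" and hetflag.strip() == "":
                polymer.append(
                    Residue(chain_id, int(seq_num), icode.strip(),
                            tables.AA3_TO_AA1[resname], atoms, "polymer")
                )
            else:
                if kind == "polymer":  # modified residue recorded as HETATM
                    kind = "ligand"
                het_groups.append(
                    Residue(chain_id, int(seq_num), icode.strip(),
                            resname, atoms, kind)
                )
        if polymer:
            chains.append(Chain(chain_id, polymer))

    if not any(c.polymer_residues() for c in chains):
        raise NoPolymerError(f"{path}: no polymer content")

    resolution = _read_resolution(path)
    return Structure(path.stem, chains, het_groups, resolution)


def _read_resolution(path: Path) -> Optional[float]:
    """REMARK 2 resolution, if present."""
    for line in path.read_text().splitlines():
        if line.startswith("REMARK   2 RESOLUTION."):
            m = re.search(r"(\d+\.\d+)\s*ANGSTROM", line)
            if m:
                return float(m.group(1))
    return None


# --- structure selection ---------------------------------------------------

def select_structures(
    candidates: Sequence[StructureMeta],
    min_coverage: int = tables.MIN_COVERAGE,
) -> list[StructureMeta]:
    """Apply the structure-mining selection rules.

    Candidates covering fewer than ``min_coverage`` reference residues are
    dropped. Among candidates with identical covered segment, ligand set
    and protein partners, only the best-resolution one is kept; candidates
    differing in ligands or partners are all retained so that liganded and
    apo (or complexed) forms are analysed separately. Survivors are ranked
    by coverage descending, then resolution ascending, then id.

    Raises :class:`NoUsableStructuresError` if nothing survives.
    """
    survivors = [c for c in candidates if c.coverage >= min_coverage]

    def _res(c: StructureMeta) -> float:
        return c.resolution if c.resolution is not None else math.inf

    best: dict[tuple, StructureMeta] = {}
    for cand in survivors:
        key = (cand.covered_range, cand.ligand_codes, cand.partner_chains)
        prev = best.get(key)
        if prev is None or (_res(cand), cand.structure_id) < (_res(prev), prev.structure_id):
            best[key] = cand

    ordered = sorted(
        best.values(),
        key=lambda c: (-c.coverage, _res(c), c.structure_id),
    )
    if not ordered:
        raise NoUsableStructuresError(
            f"no usable structures: none of {len(candidates)} candidate(s) "
            f"covers at least {min_coverage} residues"
        )
    return ordered


# --- sequence -> structure mapping ----------------------------------------

def map_sequence_to_structure(
    ref_seq: str,
    chain: Chain,
    identity_floor: float = tables.IDENTITY_FLOOR,
) -> SeqMap:
    """Map 1-based reference positions onto a chain's author-numbered residues.

    Global pairwise alignment (match +1, mismatch -1, gap open -5, gap
    extend -1) of the reference sequence against the chain's observed
    polymer sequence; gapped columns are left unmapped. Identity is the
    fraction of aligned (ungapped) columns with identical residues.

    Raises :class:`SequenceMismatchError` below ``identity_floor``.
    """
    polymer = chain.polymer_residues()
    if not polymer:
        raise NoPolymerError(f"chain {chain.chain_id} has no polymer residues")
    obs_seq = chain.sequence()

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    alignment = aligner.align(ref_seq, obs_seq)[0]

    mapping: dict[int, tuple[str, int, str]] = {}
    mismatches: set[int] = set()
    n_aligned = 0
    n_identical = 0
    for (r0, r1), (o0, o1) in zip(*alignment.aligned):
        for offset in range(r1 - r0):
            ref_idx = r0 + offset
            obs_idx = o0 + offset
            res = polymer[obs_idx]
            mapping[ref_idx + 1] = res.key
            n_aligned += 1
            if ref_seq[ref_idx] == obs_seq[obs_idx]:
                n_identical += 1
            else:
                mismatches.add(ref_idx + 1)
    identity = n_identical / n_aligned if n_aligned else 0.0
    if identity < identity_floor:
        raise SequenceMismatchError(
            f"chain {chain.chain_id}: identity {identity:.2f} below "
            f"floor {identity_floor:.2f}"
        )
    return SeqMap(mapping, identity, frozenset(mismatches))


def structure_meta(
    structure: Structure,
    target_chain_id: str,
    seqmap: SeqMap,
) -> StructureMeta:
    """Derive selection metadata for a parsed structure and mapped chain."""
    if seqmap.ref_to_structure:
        start = min(seqmap.ref_to_structure)
        end = max(seqmap.ref_to_structure) + 1
    else:
        start = end = 1
    ligands = frozenset(r.aa for r in structure.ligands())
    partners = frozenset(
        c.chain_id for c in structure.polymer_chains() if c.chain_id != target_chain_id
    )
    return StructureMeta(structure.structure_id, (start, end),
                         structure.resolution, ligands, partners)


# --- variant parsing -------------------------------------------------------

_ONE_LETTER = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_THREE_LETTER = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def parse_variant(text: str, **kwargs) -> Variant:
    """Parse ``"G12V"`` or HGVS-protein ``"p.Gly12Val"`` into a :class:`Variant`.

    Extra keyword arguments (``source``, ``clinical_label``, ``ddg``) are
    forwarded to the Variant constructor.
    """
    text = text.strip()
    m = _ONE_LETTER.match(text)
    if m:
        wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    else:
        m = _THREE_LETTER.match(text)
        if not m:
            raise VariantParseError(f"unrecognised variant string {text!r}")
        try:
            wt = tables.AA3_TO_AA1[m.group(1).upper()]
            mut = tables.AA3_TO_AA1[m.group(3).upper()]
        except KeyError as exc:
            raise VariantParseError(f"unknown amino acid in {text!r}") from exc
        pos = int(m.group(2))
    if wt not in tables.STANDARD_AA1 or mut not in tables.STANDARD_AA1:
        raise VariantParseError(f"non-standard amino acid in {text!r}")
    if wt == mut:
        raise SynonymousVariantError(f"synonymous substitution {text!r}")
    return Variant(wt, pos, mut, **kwargs)


def format_variant(v: Variant) -> str:
    """One-letter dialect round-trip partner of :func:`parse_variant`."""
    return v.short()


@dataclass(frozen=True)
class ParseIssue:
    """A row that failed to parse, with its 1-based line number."""

    line_no: int
    text: str
    message: str


@dataclass
class VariantTable:
    """Parsed variant rows plus per-line parse issues (never silently dropped)."""

    variants: list[Variant] = field(default_factory=list)
    issues: list[ParseIssue] = field(default_factory=list)

    def __iter__(self):
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __getitem__(self, idx):
        return self.variants[idx]


def read_variant_table(path: str | Path, dialect: str) -> VariantTable:
    """Read a variant table.

    Dialects:

    ``humsavar``
        Whitespace-separated rows in the UniProt curated-variant layout:
        gene, accession, feature id, ``p.Xaa123Yaa`` change, variant
        category, dbSNP id, disease. The category column is preserved
        verbatim as ``clinical_label``.
    ``clinvar``
        Tab-separated with a header; requires columns named (case- and
        space-insensitively) ``protein_change`` and
        ``clinical_significance``.
    ``simple_tsv``
        One variant per line, optional second ``ddg`` column (kcal/mol),
        optional ``variant[\\tddg]`` header.
    """
    path = Path(path)
    if dialect not in ("humsavar", "clinvar", "simple_tsv"):
        raise FileParseError(f"unknown variant-table dialect {dialect!r}")
    lines = path.read_text().splitlines()
    table = VariantTable()

    if dialect == "clinvar":
        return _read_clinvar(lines, table)

    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        try:
            if dialect == "humsavar":
                table.variants.append(_parse_humsavar_row(line))
            else:
                if line_no == 1 and line.split("\t")[0].strip().lower() == "variant":
                    continue
                table.variants.append(_parse_simple_row(line))
        except (VariantParseError, ValueError) as exc:
            table.issues.append(ParseIssue(line_no, raw, str(exc)))
    return table


def _parse_humsavar_row(line: str) -> Variant:
    fields = line.split()
    change = next((f for f in fields if f.startswith("p.")), None)
    if change is None:
        raise VariantParseError("no p.Xaa123Yaa change column")
    idx = fields.index(change)
    category = fields[idx + 1] if idx + 1 < len(fields) else None
    return parse_variant(change, source="humsavar", clinical_label=category)


def _parse_simple_row(line: str) -> Variant:
    fields = [f.strip() for f in line.split("\t")]
    ddg = None
    if len(fields) > 1 and fields[1]:
        ddg = float(fields[1])
    return parse_variant(fields[0], source="user", ddg=ddg)


def _read_clinvar(lines: list[str], table: VariantTable) -> VariantTable:
    if not lines:
        return table
    header = [h.strip().lower().replace(" ", "_") for h in lines[0].split("\t")]
    try:
        change_col = header.index("protein_change")
        signif_col = header.index("clinical_significance")
    except ValueError as exc:
        raise FileParseError(
            "clinvar dialect requires 'protein_change' and "
            "'clinical_significance' columns"
        ) from exc
    for line_no, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = [f.strip() for f in raw.split("\t")]
        try:
            if max(change_col, signif_col) >= len(fields):
                raise VariantParseError("row has too few columns")
            table.variants.append(
                parse_variant(fields[change_col], source="clinvar",
                              clinical_label=fields[signif_col] or None)
            )
        except (VariantParseError, ValueError) as exc:
            table.issues.append(ParseIssue(line_no, raw, str(exc)))
    return table
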