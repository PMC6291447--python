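"""Structure/variant input: parsing, classification, selection, mapping."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from sasdiag import fixtures
from sasdiag.errors import (
    FileParseError,
    NoPolymerError,
    NoUsableStructuresError,
    SequenceMismatchError,
    SynonymousVariantError,
    VariantParseError,
)
from sasdiag.model import Chain, StructureMeta, Variant
from sasdiag.structure_io import (
    classify_het_group,
    format_variant,
    load_solvent_list,
    map_sequence_to_structure,
    parse_variant,
    read_structure,
    read_variant_table,
    select_structures,
)
from sasdiag.tables import AA1_TO_AA3, STANDARD_AA1


# --- het classification ----------------------------------------------------

@pytest.mark.parametrize(
    "code,kind",
    [("HOH", "solvent"), ("ALA", "polymer"), ("GNP", "ligand"),
     ("SO4", "solvent"), ("NA", "solvent"), ("XXQ", "ligand")],
)
def test_het_classification(code, kind):
    assert classify_het_group(code) == kind


def test_standard_amino_acids_never_solvent():
    for aa3 in AA1_TO_AA3.values():
        assert classify_het_group(aa3) == "polymer"


def test_solvent_list_file_overrides_default(tables_dir):
    codes = load_solvent_list(tables_dir["solvents"])
    assert codes == {"HOH", "GOL", "XYZ"}
    assert classify_het_group("XYZ", codes) == "solvent"
    assert classify_het_group("SO4", codes) == "ligand"  # not in custom list


# --- PDB reading -----------------------------------------------------------

def test_read_dimer_counts(tmp_path):
    pdb, _ = fixtures.make_dimer(fixtures.FixtureSpec(n_residues=50))
    path = tmp_path / "dimer.pdb"
    path.write_text(pdb)
    struct = read_structure(path)
    assert [c.chain_id for c in struct.polymer_chains()] == ["A", "B"]
    assert sum(len(c.polymer_residues()) for c in struct.chains) == 100
    assert struct.resolution == 2.0


def test_read_liganded_structure_classifies_het(tmp_path):
    pdb, _, _ = fixtures.make_liganded_pocket()
    path = tmp_path / "lig.pdb"
    path.write_text(pdb)
    struct = read_structure(path)
    assert [r.aa for r in struct.ligands()] == ["GNP"]
    assert struct.ligands()[0].kind == "ligand"


def test_water_only_file_is_rejected(tmp_path):
    path = tmp_path / "water.pdb"
    path.write_text(
        "HETATM    1  O   HOH W   1       0.000   0.000   0.000  1.00 20.00           O\n"
        "END\n"
    )
    with pytest.raises(NoPolymerError):
        read_structure(path)


def test_target_chain_restriction(tmp_path):
    pdb, _ = fixtures.make_dimer(fixtures.FixtureSpec(n_residues=30))
    path = tmp_path / "dimer.pdb"
    path.write_text(pdb)
    struct = read_structure(path, target_chains={"B"})
    assert [c.chain_id for c in struct.polymer_chains()] == ["B"]


# --- structure selection ---------------------------------------------------

def _meta(sid, start, end, res=2.0, ligands=(), partners=()):
    return StructureMeta(sid, (start, end), res, frozenset(ligands), frozenset(partners))


def test_short_coverage_rejected_with_error():
    with pytest.raises(NoUsableStructuresError):
        select_structures([_meta("s1", 1, 20)])  # 19 residues


def test_coverage_boundary_inclusive_at_20():
    assert select_structures([_meta("s1", 1, 21)])[0].structure_id == "s1"


def test_identical_duplicates_collapse_to_best_resolution():
    out = select_structures([_meta("a", 1, 101, 2.5), _meta("b", 1, 101, 1.8)])
    # identical segment/ligands/partners: only the better resolution survives
    assert [m.structure_id for m in out] == ["b"]


def test_differing_ligands_both_retained():
    out = select_structures([
        _meta("apo", 1, 101, 2.5), _meta("holo", 1, 101, 1.8, ligands=("GNP",)),
    ])
    assert {m.structure_id for m in out} == {"apo", "holo"}
    assert out[0].structure_id == "holo"  # better resolution ranks first


def test_differing_partners_both_retained():
    out = select_structures([
        _meta("alone", 1, 101, 2.0), _meta("complex", 1, 101, 2.0, partners=("B",)),
    ])
    assert {m.structure_id for m in out} == {"alone", "complex"}


def test_coverage_ranks_before_resolution():
    out = select_structures([
        _meta("small_sharp", 1, 51, 1.0), _meta("big_blurry", 1, 101, 3.0),
    ])
    assert [m.structure_id for m in out] == ["big_blurry", "small_sharp"]


def test_selection_is_permutation_invariant():
    metas = [
        _meta(f"s{i}", 1 + i, 1 + i + 20 + i % 3, 1.5 + 0.1 * i,
              ligands=("GNP",) if i % 2 else ())
        for i in range(8)
    ]
    reference = select_structures(metas)
    rng = random.Random(0)
    for _ in range(20):
        shuffled = metas[:]
        rng.shuffle(shuffled)
        assert select_structures(shuffled) == reference


# --- sequence mapping ------------------------------------------------------

def _chain_from_pdb(tmp_path, pdb_text, chain_id="A"):
    path = tmp_path / "chain.pdb"
    path.write_text(pdb_text)
    return read_structure(path).get_chain(chain_id)


def _numbered_chain(seq, start_num):
    """Build an in-memory chain with author numbering from ``start_num``."""
    lines = []
    serial = 1
    for i, aa in enumerate(seq):
        res_lines, serial = fixtures.residue_pdb_lines(
            serial, aa, "A", start_num + i, (i * 3.8, 0.0, 0.0)
        )
        lines.extend(res_lines)
    return "\n".join(lines) + "\nEND\n"


def test_mapping_is_pure_offset_for_renumbered_chain(tmp_path):
    seq = "ALSKGDTVWE"
    chain = _chain_from_pdb(tmp_path, _numbered_chain(seq, 100))
    seqmap = map_sequence_to_structure(seq, chain)
    assert seqmap.identity == 1.0
    for i in range(1, len(seq) + 1):
        assert seqmap[i] == ("A", 99 + i, "")


def test_missing_loop_leaves_positions_unmapped(tmp_path):
    ref = "ALSKGDTVWEALSKGDTVWE"
    observed = ref[:8] + ref[13:]  # drop an internal 5-residue loop
    chain = _chain_from_pdb(tmp_path, _numbered_chain(observed, 1))
    seqmap = map_sequence_to_structure(ref, chain)
    unmapped = {p for p in range(1, 21) if p not in seqmap}
    assert unmapped == {9, 10, 11, 12, 13}
    assert seqmap[8] == ("A", 8, "")
    assert seqmap[14] == ("A", 9, "")


def test_unrelated_sequence_raises_mismatch(tmp_path):
    chain = _chain_from_pdb(tmp_path, _numbered_chain("ALSKGDTVWE", 1))
    with pytest.raises(SequenceMismatchError):
        map_sequence_to_structure("PPPPPPPPPP", chain)


def test_identity_mapping_roundtrip(tmp_path):
    """For identical sequences the map composed with its inverse is identity."""
    seq = "GAVLIMFWPSTCYNQDEKRH"
    chain = _chain_from_pdb(tmp_path, _numbered_chain(seq, 7))
    seqmap = map_sequence_to_structure(seq, chain)
    inverse = {v: k for k, v in seqmap.ref_to_structure.items()}
    assert len(inverse) == len(seqmap.ref_to_structure)  # injective
    for ref_pos, key in seqmap.ref_to_structure.items():
        assert inverse[key] == ref_pos


# --- variant parsing -------------------------------------------------------

def test_parse_one_letter_dialect():
    v = parse_variant("G12V")
    assert (v.wt_aa, v.position, v.mut_aa) == ("G", 12, "V")


def test_parse_hgvs_dialect_equivalent():
    assert parse_variant("p.Gly12Val") == parse_variant("G12V")


def test_synonymous_rejected():
    with pytest.raises(SynonymousVariantError):
        parse_variant("G12G")


@pytest.mark.parametrize("bad", ["G12", "12V", "p.Gly12", "B12V", "G0V", "banana"])
def test_malformed_variants_rejected(bad):
    with pytest.raises((VariantParseError, ValueError)):
        parse_variant(bad)


@settings(max_examples=200, derandomize=True)
@given(
    wt=st.sampled_from(sorted(STANDARD_AA1)),
    mut=st.sampled_from(sorted(STANDARD_AA1)),
    pos=st.integers(min_value=1, max_value=99999),
)
def test_variant_format_parse_roundtrip(wt, mut, pos):
    if wt == mut:
        return
    v = Variant(wt, pos, mut)
    assert parse_variant(format_variant(v)) == v


# --- variant tables --------------------------------------------------------

def test_humsavar_table_counts_and_error_report(tables_dir):
    table = read_variant_table(tables_dir["humsavar"], "humsavar")
    assert len(table) == 10
    assert sum(v.clinical_label == "LP/P" for v in table) == 3
    assert [issue.line_no for issue in table.issues] == [7]


def test_clinvar_table(tables_dir):
    table = read_variant_table(tables_dir["clinvar"], "clinvar")
    assert len(table) == 3
    assert table[0].clinical_label == "Pathogenic"
    assert table[2].key == ("L", 7, "P")


def test_simple_tsv_carries_ddg(tables_dir):
    table = read_variant_table(tables_dir["variants"], "simple_tsv")
    assert table[0].ddg == 3.25
    assert table[3].ddg is None


def test_empty_table_gives_empty_list(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("")
    assert len(read_variant_table(p, "simple_tsv")) == 0


def test_bad_position_reported_with_line_number(tmp_path):
    p = tmp_path / "v.tsv"
    p.write_text("G12V\nG12xV\nA3T\n")
    table = read_variant_table(p, "simple_tsv")
    assert len(table) == 2
    assert [i.line_no for i in table.issues] == [2]


def test_unknown_dialect_rejected(tmp_path):
    p = tmp_path / "v.tsv"
    p.write_text("G12V\n")
    with pytest.raises(FileParseError):
        read_variant_table(p, "nonsense")
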