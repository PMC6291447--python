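"""Synthetic structure and table generators.

Everything the pipeline reads can be generated here with controlled
geometry and machine-readable ground truth, so the whole package is
exercised offline. Chains are idealised: residues are rigid five-atom
templates (N, CA, C, O, CB; no CB for glycine) strung along the x axis —
every rule under test is geometric or tabular, so backbone realism is not
required. All randomness flows through the ``seed`` of the spec; the
same seed gives byte-identical files.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .model import Atom, Chain, Residue, ResidueKey, Structure
from .tables import AA1_TO_AA3

__all__ = [
    "FixtureSpec",
    "residue_pdb_lines",
    "make_dimer",
    "random_dimer_structure",
    "make_liganded_pocket",
    "make_burial_shell",
    "make_tables",
    "make_full_demo",
]

SPACING = 3.8  # Å between consecutive CA atoms along x

#: atom name -> (dx, dy, dz) offsets from the CA position
_TEMPLATE = {
    "N": (-1.2, 0.8, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.2, 0.8, 0.0),
    "O": (1.2, 2.0, 0.0),
    "CB": (0.0, -1.53, 0.0),
}


@dataclass
class FixtureSpec:
    """Parameters shared by the geometric generators."""

    seed: int = 0
    n_residues: int = 50
    separation: float = 8.0          # Å between the two chains (z offset)
    contact_residues: tuple[int, ...] = ()
    contact_separation: float = 4.0  # Å z offset for the contact patch
    spacing: float = SPACING
    cutoff: float = 5.0              # interface cutoff the truth is built for


def _atom_line(serial: int, name: str, resname: str, chain: str, resnum: int,
               x: float, y: float, z: float, b: float, element: str,
               het: bool = False) -> str:
    record = "HETATM" if het else "ATOM"
    name_field = f" {name:<3}" if len(name) < 4 else name[:4]
    return (
        f"{record:<6}{serial:>5} {name_field}{'':1}{resname:>3} {chain:1}"
        f"{resnum:>4}{'':1}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}"
        f"          {element:>2}"
    )


def residue_pdb_lines(serial: int, aa: str, chain: str, resnum: int,
                      ca_pos: tuple[float, float, float],
                      b: float = 20.0) -> tuple[list[str], int]:
    """PDB lines for one template residue; returns (lines, next serial)."""
    lines = []
    for name, (dx, dy, dz) in _TEMPLATE.items():
        if name == "CB" and aa == "G":
            continue
        element = name[0]
        lines.append(
            _atom_line(serial, name, AA1_TO_AA3[aa], chain, resnum,
                       ca_pos[0] + dx, ca_pos[1] + dy, ca_pos[2] + dz, b, element)
        )
        serial += 1
    return lines, serial


def _min_template_distance(offset: int, spacing: float, dz: float, aa_a: str = "G",
                           aa_b: str = "G") -> float:
    """Closest heavy-atom distance between template residues ``offset``
    positions apart in x and ``dz`` apart in z — derived directly from the
    template offsets, independent of any neighbour-search code."""
    best = math.inf
    for na, (ax, ay, _) in _TEMPLATE.items():
        if na == "CB" and aa_a == "G":
            continue
        for nb, (bx, by, _) in _TEMPLATE.items():
            if nb == "CB" and aa_b == "G":
                continue
            d = math.sqrt((offset * spacing + bx - ax) ** 2 + (by - ay) ** 2 + dz ** 2)
            best = min(best, d)
    return best


def make_dimer(spec: FixtureSpec, sequence_a: Optional[str] = None,
               sequence_b: Optional[str] = None) -> tuple[str, set[ResidueKey]]:
    """Two parallel idealised chains with an optional contact patch.

    Chain B sits ``spec.separation`` Å above chain A except at
    ``spec.contact_residues``, lowered to ``spec.contact_separation`` Å.
    Returns the PDB text and the ground-truth interface set for
    ``spec.cutoff``, computed analytically from the template offsets.
    """
    n = spec.n_residues
    seq_a = (sequence_a or "G" * n).upper()
    seq_b = (sequence_b or "G" * n).upper()
    patch = set(spec.contact_residues)

    lines = ["REMARK   2 RESOLUTION.    2.00 ANGSTROMS."]
    serial = 1
    for i in range(1, n + 1):
        res_lines, serial = residue_pdb_lines(serial, seq_a[i - 1], "A", i,
                                              ((i - 1) * spec.spacing, 0.0, 0.0))
        lines.extend(res_lines)
    for i in range(1, n + 1):
        z = spec.contact_separation if i in patch else spec.separation
        res_lines, serial = residue_pdb_lines(serial, seq_b[i - 1], "B", i,
                                              ((i - 1) * spec.spacing, 0.0, z))
        lines.extend(res_lines)
    lines.append("END")

    truth: set[ResidueKey] = set()
    for i in patch:
        dz = spec.contact_separation
        for offset in range(-3, 4):
            j = i + offset
            if not 1 <= j <= n:
                continue
            d = _min_template_distance(abs(offset), spec.spacing, dz,
                                       seq_a[j - 1], seq_b[i - 1])
            if d < spec.cutoff:
                truth.add(("A", j, ""))
                truth.add(("B", i, ""))
    # contacts between patch and non-patch rows of chain B are same-chain
    # and therefore never interface; chain B at full separation never
    # reaches chain A when separation >= cutoff
    if spec.separation < spec.cutoff:
        for i in range(1, n + 1):
            if i in patch:
                continue
            for offset in range(-3, 4):
                j = i + offset
                if 1 <= j <= n and _min_template_distance(
                    abs(offset), spec.spacing, spec.separation,
                    seq_a[j - 1], seq_b[i - 1],
                ) < spec.cutoff:
                    truth.add(("A", j, ""))
                    truth.add(("B", i, ""))
    return "\n".join(lines) + "\n", truth


def random_dimer_structure(seed: int, n_per_chain: int = 50) -> Structure:
    """A random two-chain structure (in-memory) for oracle-equivalence
    tests: residues of 1-4 carbon atoms scattered in two overlapping
    boxes. No ground truth — compare implementations against each other."""
    rng = random.Random(seed)
    chains = []
    for ci, chain_id in enumerate(("A", "B")):
        residues = []
        for i in range(1, n_per_chain + 1):
            center = (
                rng.uniform(0.0, 40.0),
                rng.uniform(0.0, 20.0),
                rng.uniform(0.0, 12.0) + (6.0 if ci else 0.0),
            )
            atoms = []
            for k in range(rng.randint(1, 4)):
                atoms.append(
                    Atom(
                        name=f"C{k}" if k else "CA",
                        element="C",
                        coords=(
                            center[0] + rng.uniform(-1.5, 1.5),
                            center[1] + rng.uniform(-1.5, 1.5),
                            center[2] + rng.uniform(-1.5, 1.5),
                        ),
                        b_factor=rng.uniform(5.0, 60.0),
                    )
                )
            residues.append(Residue(chain_id, i, "", "A", atoms, "polymer"))
        chains.append(Chain(chain_id, residues))
    return Structure(f"rand{seed}", chains)


def make_liganded_pocket(
    n_residues: int = 40,
    ligand_residues: tuple[int, ...] = (10, 11, 14),
    ligand_distance: float = 3.5,
    ligand_code: str = "GNP",
    pocket_residues: tuple[int, ...] = (30, 31, 32, 33, 34, 35),
    druggability: float = 0.62,
    spacing: float = SPACING,
) -> tuple[str, str, set[ResidueKey]]:
    """A single chain with a ligand planted below chosen residues.

    The chain is glycine except ALA at the ligand target residues; one
    ligand heavy atom sits ``ligand_distance`` Å below each target CB, so
    the expected ligand-contact set is exactly the targets (neighbouring
    glycine backbones stay outside 5 Å by construction). Also writes a
    pocket-info file (one scored pocket over ``pocket_residues`` and one
    low-scoring decoy). Returns (pdb text, pocket text, contact truth).
    """
    seq = "".join("A" if i in ligand_residues else "G" for i in range(1, n_residues + 1))
    lines = ["REMARK   2 RESOLUTION.    1.90 ANGSTROMS."]
    serial = 1
    for i in range(1, n_residues + 1):
        res_lines, serial = residue_pdb_lines(serial, seq[i - 1], "A", i,
                                              ((i - 1) * spacing, 0.0, 0.0))
        lines.extend(res_lines)
    cb_y = _TEMPLATE["CB"][1]
    for k, i in enumerate(sorted(ligand_residues), start=1):
        lines.append(
            _atom_line(serial, f"C{k}", ligand_code, "L", 1,
                       (i - 1) * spacing, cb_y - ligand_distance, 0.0, 30.0, "C",
                       het=True)
        )
        serial += 1
    lines.append("END")
    truth = {("A", i, "") for i in ligand_residues}

    pocket_text = (
        "Pocket 1 :\n"
        f"\tDruggability Score : {druggability}\n"
        "\tResidues : " + " ".join(f"A:{i}" for i in pocket_residues) + "\n"
        "Pocket 2 :\n"
        "\tDruggability Score : 0.18\n"
        "\tResidues : A:2 A:3\n"
    )
    return "\n".join(lines) + "\n", pocket_text, truth


def _fibonacci_sphere(n: int, radius: float, center: tuple[float, float, float]):
    idx = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * idx / n)
    theta = np.pi * (1.0 + 5.0**0.5) * idx
    return np.column_stack(
        (
            center[0] + radius * np.cos(theta) * np.sin(phi),
            center[1] + radius * np.sin(theta) * np.sin(phi),
            center[2] + radius * np.cos(phi),
        )
    )


def make_burial_shell(
    n_residues: int = 9,
    buried_pos: int = 2,
    exposed_pos: int = 8,
    shell_points: int = 64,
    shell_radius: float = 4.5,
    spacing: float = SPACING,
) -> tuple[str, dict[int, Optional[bool]]]:
    """One chain with a residue sealed inside a dense same-chain atom shell.

    The buried ALA's CB is enclosed by ``shell_points`` carbon atoms (as
    extra single-atom ALA residues of the same chain, so they confer no
    interface or binding label) at ``shell_radius`` Å: no probe position
    on the CB's accessible sphere clears the shell, so its sidechain SASA
    is exactly zero. A second ALA far along the chain is fully free.
    Returns (pdb text, expected exposed/buried map: True=exposed,
    False=buried, None=glycine unlabelled).
    """
    seq = "".join(
        "A" if i in (buried_pos, exposed_pos) else "G" for i in range(1, n_residues + 1)
    )
    lines = ["REMARK   2 RESOLUTION.    2.10 ANGSTROMS."]
    serial = 1
    for i in range(1, n_residues + 1):
        res_lines, serial = residue_pdb_lines(serial, seq[i - 1], "A", i,
                                              ((i - 1) * spacing, 0.0, 0.0))
        lines.extend(res_lines)
    cb = ((buried_pos - 1) * spacing, _TEMPLATE["CB"][1], 0.0)
    for k, pos in enumerate(_fibonacci_sphere(shell_points, shell_radius, cb)):
        lines.append(
            _atom_line(serial, "CB", "ALA", "A", 100 + k,
                       float(pos[0]), float(pos[1]), float(pos[2]), 20.0, "C")
        )
        serial += 1
    lines.append("END")
    truth: dict[int, Optional[bool]] = {
        i: None for i in range(1, n_residues + 1) if seq[i - 1] == "G"
    }
    truth[buried_pos] = False
    truth[exposed_pos] = True
    return "\n".join(lines) + "\n", truth


# --- tables -----------------------------------------------------------------

def make_tables(out_dir: str | Path, seed: int = 0,
                include_malformed: bool = True) -> dict[str, Path]:
    """Write one file in every table dialect the readers accept, with
    planted values (and, optionally, deliberately malformed lines for the
    error paths). Returns a name -> path map; planted ground truth is in
    the companion ``truth`` entry semantics documented per file below.

    * ``variants.tsv`` — simple dialect, 4 rows, ddg column; row 1 ddg 3.25.
    * ``humsavar.txt`` — 10 rows, 3 disease-flagged (``LP/P``); malformed
      row on line 7 when enabled.
    * ``clinvar.tsv`` — 3 rows, one pathogenic.
    * ``foldx_dif.fxout`` — BuildModel difference dialect; GA12V ddg 3.25.
    * ``stability_wt.fxout`` / ``stability_mut.fxout`` — paired energies
      10.0 / 12.5 (ddg 2.5).
    * ``family.fasta`` — 4-row MSA: column 1 all-L, column 2 uniform A/V,
      column 3 mixed.
    * ``catalog.csv`` — catalytic rows for structure id ``fix1``.
    * ``did3.tsv``, ``pockets.txt``, ``solvents.txt``, ``switch.tsv``.
    """
    rng = random.Random(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["variants"] = out / "variants.tsv"
    paths["variants"].write_text(
        "variant\tddg\nG12V\t3.25\nA33T\t0.50\nL7P\t2.75\nK40E\t\n"
    )

    genes = ["GN1A", "GN2B", "GN3C"]
    rows = []
    aas = ["Gly", "Ala", "Leu", "Val", "Ser", "Thr", "Arg", "Glu"]
    for i in range(10):
        wt, mut = rng.sample(aas, 2)
        pos = rng.randint(2, 200)
        category = "LP/P" if i < 3 else "LB/B"
        rows.append(
            f"{rng.choice(genes):<10} P{10000 + i}     VAR_{i:06d}  "
            f"p.{wt}{pos}{mut}   {category}   rs{1000 + i}   -"
        )
    if include_malformed:
        rows.insert(6, "GN9X       P99999     VAR_999999  p.Gly12xVal   LP/P   rs9   -")
    paths["humsavar"] = out / "humsavar.txt"
    paths["humsavar"].write_text("\n".join(rows) + "\n")

    paths["clinvar"] = out / "clinvar.tsv"
    paths["clinvar"].write_text(
        "protein_change\tclinical_significance\n"
        "G12V\tPathogenic\nA33T\tBenign\np.Leu7Pro\tLikely pathogenic\n"
    )

    paths["foldx_dif"] = out / "foldx_dif.fxout"
    paths["foldx_dif"].write_text(
        "# BuildModel energy differences (kcal/mol)\n"
        "GA12V;\t3.25\nAA33T;\t0.5\nLA7P;\t2.75\n"
    )
    paths["stability_wt"] = out / "stability_wt.fxout"
    paths["stability_wt"].write_text("wild.pdb\t10.0\n")
    paths["stability_mut"] = out / "stability_mut.fxout"
    paths["stability_mut"].write_text("mutant.pdb\t12.5\n")

    # column 1: all L; column 2: 2xA + 2xV; column 3: mixed; column 4 gap-heavy
    msa_rows = ["LAGK", "LAG-", "LVSK", "LVGK"]
    paths["msa"] = out / "family.fasta"
    paths["msa"].write_text(
        "".join(f">seq{i}\n{row}\n" for i, row in enumerate(msa_rows))
    )

    paths["catalog"] = out / "catalog.csv"
    paths["catalog"].write_text(
        "structure_id,chain,resnum,role\n"
        "fix1,A,57,nucleophile\nfix1,A,102,acid\nfix1,A,9999,ghost\n"
        "other,A,1,unrelated\n"
    )

    paths["did3"] = out / "did3.tsv"
    paths["did3"].write_text("A\t12\nA\t13\n")

    _, pocket_text, _ = make_liganded_pocket()
    paths["pockets"] = out / "pockets.txt"
    paths["pockets"].write_text(pocket_text)

    paths["solvents"] = out / "solvents.txt"
    paths["solvents"].write_text("# extra buffer codes\nHOH\nGOL\nXYZ\n")

    paths["switch"] = out / "switch.tsv"
    paths["switch"].write_text("position\tscore\n1\t0\n2\t1\n3\t0\n")
    return paths


# --- end-to-end demo --------------------------------------------------------

@dataclass
class DemoFixture:
    """The four-variant end-to-end fixture: paths plus expected outcome."""

    ref_seq: str
    structures: list[Path]
    variant_table: Path
    foldx: dict[str, Path]
    expected_labels: dict[str, str]
    expected_interface: set[ResidueKey] = field(default_factory=set)
    expected_binding: set[ResidueKey] = field(default_factory=set)


def make_full_demo(out_dir: str | Path, seed: int = 0) -> DemoFixture:
    """Write the planted-outcome demo: a liganded dimer and an apo form.

    Chain A (40 template residues + 64 shell residues): ALA at 5
    (exposed surface), 10 (ligand contact), 22 (interface patch), 30
    (sealed in a shell); glycine elsewhere. Chain B (11 glycines) floats
    above A16-A26 with residue 7 lowered into contact over A22. A GNP
    heavy atom sits 3.5 Å below A10's CB; a water sits 4.5 Å below A15
    (solvent: must not create a binding label). Variants A5V/A10V/A22V/
    A30V with ddG 0.1/3.0/3.0/3.0 from a difference table must diagnose,
    after aggregation over both crystal forms, as: likely non pathogenic /
    disrupt function / disrupt interface / disrupt folding.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_a, n_b, shell_n = 40, 11, 64
    special = {5: "A", 10: "A", 22: "A", 30: "A"}
    seq_a = "".join(special.get(i, "G") for i in range(1, n_a + 1))
    ref_seq = seq_a + "A" * shell_n

    def chain_lines(with_ligand: bool) -> list[str]:
        lines = []
        serial = 1
        for i in range(1, n_a + 1):
            b = 40.0 if i == 22 else 20.0
            res_lines, serial = residue_pdb_lines(
                serial, seq_a[i - 1], "A", i, ((i - 1) * SPACING, 0.0, 0.0), b=b
            )
            lines.extend(res_lines)
        cb30 = ((30 - 1) * SPACING, _TEMPLATE["CB"][1], 0.0)
        for k, pos in enumerate(_fibonacci_sphere(shell_n, 4.5, cb30)):
            lines.append(
                _atom_line(serial, "CB", "ALA", "A", 100 + k,
                           float(pos[0]), float(pos[1]), float(pos[2]), 20.0, "C")
            )
            serial += 1
        for j in range(1, n_b + 1):
            z = 4.0 if j == 7 else 9.0
            x = (15 + j - 1) * SPACING
            res_lines, serial = residue_pdb_lines(serial, "G", "B", j, (x, 0.0, z))
            lines.extend(res_lines)
        if with_ligand:
            lines.append(
                _atom_line(serial, "C1", "GNP", "L", 1,
                           (10 - 1) * SPACING, _TEMPLATE["CB"][1] - 3.5, 0.0,
                           30.0, "C", het=True)
            )
            serial += 1
        lines.append(
            _atom_line(serial, "O", "HOH", "W", 1,
                       (15 - 1) * SPACING, _TEMPLATE["CB"][1] - 4.5 + 1.53, 0.0,
                       30.0, "O", het=True)
        )
        lines.append("END")
        return lines

    holo = out / "demo_holo.pdb"
    holo.write_text(
        "\n".join(["REMARK   2 RESOLUTION.    1.80 ANGSTROMS."] + chain_lines(True)) + "\n"
    )
    apo = out / "demo_apo.pdb"
    apo.write_text(
        "\n".join(["REMARK   2 RESOLUTION.    2.30 ANGSTROMS."] + chain_lines(False)) + "\n"
    )

    variant_table = out / "demo_variants.tsv"
    variant_table.write_text("variant\nA5V\nA10V\nA22V\nA30V\n")

    dif_text = "AA5V;\t0.1\nAA10V;\t3.0\nAA22V;\t3.0\nAA30V;\t3.0\n"
    foldx = {}
    for sid in ("demo_holo", "demo_apo"):
        p = out / f"{sid}.dif.fxout"
        p.write_text(dif_text)
        foldx[sid] = p

    expected_interface = {("A", 21, ""), ("A", 22, ""), ("A", 23, ""), ("B", 7, "")}
    return DemoFixture(
        ref_seq=ref_seq,
        structures=[holo, apo],
        variant_table=variant_table,
        foldx=foldx,
        expected_labels={
            "A5V": "Likely non pathogenic mutation",
            "A10V": "Disrupt protein function",
            "A22V": "Disrupt protein interface",
            "A30V": "Disrupt protein folding",
        },
        expected_interface=expected_interface,
        expected_binding={("A", 10, "")},
    )
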