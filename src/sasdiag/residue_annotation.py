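"""Per-residue structural annotation.

Computes the per-structure labels consumed by the diagnosis stage:

* sidechain solvent exposure (Shrake-Rupley SASA relative to a per-residue
  maximal-sidechain reference; glycine is never labelled),
* protein-protein interface membership (heavy-atom pairs across polymer
  chains closer than a strict 5 Å cutoff),
* ligand contacts and pocket-based binding labels,
* catalytic labels from a curated catalog,
* the informational 3did label and median-relative B-factor.

The SASA implementation is a deterministic Shrake-Rupley: sphere points
come from a golden-section spiral (no RNG), neighbour search uses a k-d
tree but is contractually identical to the all-pairs rule.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from . import tables
from .errors import ConfigError, FileParseError
from .model import Residue, ResidueKey, Structure

__all__ = [
    "Pocket",
    "ResidueAnnotation",
    "sphere_points",
    "compute_sasa",
    "sidechain_exposure",
    "interface_residues",
    "ligand_contact_residues",
    "read_pockets",
    "read_did3",
    "binding_residues",
    "catalytic_residues",
    "relative_bfactor",
    "annotate_structure",
    "write_annotation_tsv",
]

#: SASA map: (residue key, atom name) -> accessible area in Å².
SasaMap = dict[tuple[ResidueKey, str], float]


@dataclass(frozen=True)
class Pocket:
    """A surface pocket: member residues plus a 0-1 druggability score."""

    pocket_id: int
    residues: frozenset[ResidueKey]
    druggability: float
    contains_ligand: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"pocket {self.pocket_id} has no residues")
        if not 0.0 <= self.druggability <= 1.0:
            raise ValueError(
                f"pocket {self.pocket_id}: druggability {self.druggability} "
                "outside [0, 1]"
            )


@dataclass
class ResidueAnnotation:
    """All per-residue flags and values for one structure.

    ``exposure_pct``/``exposed`` are ``None`` for glycine, which has no
    sidechain and is never partitioned into buried/exposed.
    """

    key: ResidueKey
    aa: str
    exposure_pct: Optional[float]
    exposed: Optional[bool]
    interface: bool
    did3: bool
    binding: bool
    catalytic: bool
    rel_bfactor: float


# --- solvent accessible surface area --------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """``n`` nearly uniform unit-sphere points on a golden-section spiral."""
    idx = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * idx / n)
    theta = np.pi * (1.0 + 5.0**0.5) * idx
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _sasa_atoms(structure: Structure) -> list[tuple[ResidueKey, str, str, np.ndarray]]:
    """Heavy atoms entering the SASA computation.

    Polymer residues and ligand het-groups contribute; solvent molecules
    are stripped first, as is standard before surface analysis.
    """
    out = []
    for res in structure.residues():
        if res.kind == "solvent":
            continue
        for atom in res.heavy_atoms():
            out.append((res.key, atom.name, atom.element, np.asarray(atom.coords)))
    return out


def compute_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] = tables.VDW_RADII,
) -> SasaMap:
    """Shrake-Rupley solvent accessible surface area per heavy atom (Å²).

    Deterministic for a fixed ``n_points``: test points are a fixed
    golden-spiral lattice on each atom's probe-expanded sphere; a point is
    accessible when it lies inside no other atom's expanded sphere.

    Raises :class:`ConfigError` listing any element without a radius.
    """
    atoms = _sasa_atoms(structure)
    if not atoms:
        return {}
    missing = sorted({el for _, _, el, _ in atoms if el not in radii})
    if missing:
        raise ConfigError(f"no van der Waals radius for element(s): {', '.join(missing)}")

    coords = np.array([c for _, _, _, c in atoms])
    expanded = np.array([radii[el] + probe_radius for _, _, el, _ in atoms])
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = expanded.max()

    out: SasaMap = {}
    for i, (key, name, _el, center) in enumerate(atoms):
        r_i = expanded[i]
        neighbours = [
            j for j in tree.query_ball_point(center, r_i + max_r)
            if j != i and np.linalg.norm(coords[j] - center) < r_i + expanded[j]
        ]
        if neighbours:
            pts = center + r_i * unit
            d2 = ((pts[:, None, :] - coords[neighbours][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[neighbours] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[(key, name)] = float(4.0 * np.pi * r_i**2 * frac)
    return out


def sidechain_exposure(
    structure: Structure,
    residue: Residue,
    sasa: SasaMap,
    max_sidechain_sasa: dict[str, float] = tables.MAX_SIDECHAIN_SASA,
    threshold: float = tables.EXPOSURE_THRESHOLD,
) -> tuple[Optional[float], Optional[bool]]:
    """Relative sidechain exposure and the exposed/buried verdict.

    Exposure is the residue's in-context sidechain SASA as a percentage of
    the per-residue-type maximal sidechain SASA, capped at 100. Residues
    strictly above ``threshold`` percent are exposed, otherwise buried.
    Glycine, having no sidechain, gets ``(None, None)`` and never enters
    the partition.
    """
    try:
        structure.find_residue(residue.key)
    except KeyError:
        raise KeyError(f"residue {residue.key} not part of {structure.structure_id}")
    if residue.aa == "G":
        return None, None
    reference = max_sidechain_sasa.get(residue.aa)
    if reference is None or reference <= 0:
        raise ConfigError(f"no maximal sidechain SASA for residue type {residue.aa!r}")
    area = float(sum(sasa.get((residue.key, a.name), 0.0) for a in residue.sidechain_atoms()))
    pct = min(100.0 * area / reference, 100.0)
    return pct, bool(pct > threshold)


# --- contacts --------------------------------------------------------------

def interface_residues(
    structure: Structure,
    cutoff: float = tables.INTERFACE_CUTOFF,
) -> set[ResidueKey]:
    """Residues with a heavy atom strictly closer than ``cutoff`` to a heavy
    atom of a *different* polymer chain. Symmetric: both partners are
    labelled. Structures with fewer than two polymer chains give an empty
    set."""
    chains = structure.polymer_chains()
    if len(chains) < 2:
        return set()
    keys: list[ResidueKey] = []
    chain_idx: list[int] = []
    coords: list[tuple[float, float, float]] = []
    for ci, chain in enumerate(chains):
        for res in chain.polymer_residues():
            for atom in res.heavy_atoms():
                keys.append(res.key)
                chain_idx.append(ci)
                coords.append(atom.coords)
    pts = np.asarray(coords)
    cidx = np.asarray(chain_idx)
    tree = cKDTree(pts)
    out: set[ResidueKey] = set()
    for i, j in tree.query_pairs(cutoff):
        if cidx[i] != cidx[j] and np.linalg.norm(pts[i] - pts[j]) < cutoff:
            out.add(keys[i])
            out.add(keys[j])
    return out


def ligand_contact_residues(
    structure: Structure,
    cutoff: float = tables.LIGAND_CONTACT_CUTOFF,
) -> set[ResidueKey]:
    """Polymer residues with a heavy atom strictly closer than ``cutoff`` to
    a heavy atom of a ligand-kind het-group. Solvent never contributes."""
    ligand_coords = [
        a.coords for lig in structure.ligands() for a in lig.heavy_atoms()
    ]
    if not ligand_coords:
        return set()
    keys: list[ResidueKey] = []
    coords: list[tuple[float, float, float]] = []
    for chain in structure.polymer_chains():
        for res in chain.polymer_residues():
            for atom in res.heavy_atoms():
                keys.append(res.key)
                coords.append(atom.coords)
    pts = np.asarray(coords)
    tree = cKDTree(pts)
    out: set[ResidueKey] = set()
    for lc in np.asarray(ligand_coords):
        for i in tree.query_ball_point(lc, cutoff):
            if np.linalg.norm(pts[i] - lc) < cutoff:
                out.add(keys[i])
    return out


# --- pockets / catalogs ----------------------------------------------------

_POCKET_HEADER = re.compile(r"^Pocket\s+(\d+)\s*:?\s*$")
_RESIDUE_TOKEN = re.compile(r"^([A-Za-z0-9]):(-?\d+)(?::([A-Za-z]))?$")


def read_pockets(
    path: str | Path,
    structure: Optional[Structure] = None,
    ligand_cutoff: float = tables.LIGAND_CONTACT_CUTOFF,
) -> list[Pocket]:
    """Read a pocket-info file (fpocket-style dialect).

    Blocks look like::

        Pocket 1 :
            Druggability Score : 0.62
            Residues : A:30 A:31 A:32

    Residue tokens are ``chain:resnum`` with an optional ``:icode``.
    If ``structure`` is supplied, ``contains_ligand`` is set when any
    ligand heavy atom lies strictly closer than ``ligand_cutoff`` to a
    heavy atom of a pocket residue.
    """
    blocks: list[tuple[int, float | None, list[ResidueKey]]] = []
    current: Optional[list] = None
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = _POCKET_HEADER.match(line)
        if m:
            current = [int(m.group(1)), None, []]
            blocks.append(current)
            continue
        if current is None:
            raise FileParseError(f"line {line_no}: content outside any pocket block")
        if ":" not in line:
            raise FileParseError(f"line {line_no}: expected 'Key : value'")
        key, _, value = line.partition(":")
        key = key.strip().lower()
        if key == "druggability score":
            try:
                current[1] = float(value.strip())
            except ValueError:
                raise FileParseError(f"line {line_no}: bad druggability score {value!r}")
        elif key == "residues":
            for tok in value.split():
                tm = _RESIDUE_TOKEN.match(tok)
                if not tm:
                    raise FileParseError(f"line {line_no}: bad residue token {tok!r}")
                current[2].append((tm.group(1), int(tm.group(2)), tm.group(3) or ""))
        # other keys (Score, Volume, ...) are ignored

    pockets: list[Pocket] = []
    for i, (pid, score, residues) in enumerate(blocks, start=1):
        if score is None:
            raise FileParseError(f"pocket block {i}: missing 'Druggability Score' line")
        if not residues:
            raise FileParseError(f"pocket block {i}: missing or empty 'Residues' line")
        contains = False
        if structure is not None:
            contains = _pocket_has_ligand(structure, residues, ligand_cutoff)
        pockets.append(Pocket(pid, frozenset(residues), score, contains))
    return pockets


def _pocket_has_ligand(
    structure: Structure, residues: Iterable[ResidueKey], cutoff: float
) -> bool:
    pocket_coords = []
    wanted = set(residues)
    for chain in structure.polymer_chains():
        for res in chain.polymer_residues():
            if res.key in wanted:
                pocket_coords.extend(a.coords for a in res.heavy_atoms())
    if not pocket_coords:
        return False
    tree = cKDTree(np.asarray(pocket_coords))
    for lig in structure.ligands():
        for atom in lig.heavy_atoms():
            d, _ = tree.query(atom.coords)
            if d < cutoff:
                return True
    return False


def binding_residues(
    structure: Structure,
    pockets: Iterable[Pocket],
    contacts: set[ResidueKey],
    druggability_threshold: float = tables.DRUGGABILITY_THRESHOLD,
) -> set[ResidueKey]:
    """Binding label: ligand contacts plus every residue of each pocket with
    druggability strictly above threshold and/or a ligand inside it. All
    residues of a qualifying pocket count, even those not touching the
    ligand."""
    out = set(contacts)
    for pocket in pockets:
        if pocket.druggability > druggability_threshold or pocket.contains_ligand:
            out |= pocket.residues
    return out


def catalytic_residues(
    catalog_path: str | Path,
    structure_id: str,
    structure: Structure,
) -> tuple[set[ResidueKey], list[dict]]:
    """Catalytic labels from a catalytic-site catalog (CSV with columns
    ``structure_id, chain, resnum[, role]``).

    Returns the residue keys present in both catalog and structure, plus a
    report of catalog rows referencing residues absent from the structure.
    """
    present: set[ResidueKey] = set()
    missing: list[dict] = []
    known = {
        res.key
        for chain in structure.polymer_chains()
        for res in chain.polymer_residues()
    }
    with open(catalog_path, newline="") as fh:
        for row in csv.DictReader(fh):
            if row.get("structure_id", "").strip() != structure_id:
                continue
            try:
                key = (row["chain"].strip(), int(row["resnum"]), "")
            except (KeyError, ValueError):
                missing.append({**row, "reason": "malformed row"})
                continue
            if key in known:
                present.add(key)
            else:
                missing.append({**row, "reason": "residue not in structure"})
    return present, missing


def read_did3(path: str | Path) -> set[ResidueKey]:
    """Read a domain-domain-interface residue list (TSV ``chain<TAB>resnum``).

    These labels are informational only: they mark a residue as belonging
    to a known domain-domain interface without setting the geometric
    interface flag, and they never enter the diagnosis tree.
    """
    out: set[ResidueKey] = set()
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FileParseError(f"line {line_no}: expected 'chain<TAB>resnum'")
        try:
            out.add((fields[0].strip(), int(fields[1]), ""))
        except ValueError:
            raise FileParseError(f"line {line_no}: bad residue number {fields[1]!r}")
    return out


# --- B-factor ---------------------------------------------------------------

def relative_bfactor(structure: Structure, residue: Residue) -> float:
    """Residue mean heavy-atom B-factor over the protein-wide median of
    per-residue means. An all-zero (or zero-median) B-factor column gives
    the neutral ratio 1.0."""
    means = [
        r.mean_bfactor()
        for chain in structure.polymer_chains()
        for r in chain.polymer_residues()
    ]
    median = float(np.median(means)) if means else 0.0
    if median <= 0.0:
        return 1.0
    return residue.mean_bfactor() / median


# --- assembly ---------------------------------------------------------------

def annotate_structure(
    structure: Structure,
    pockets: Iterable[Pocket] = (),
    catalytic: set[ResidueKey] | None = None,
    did3: set[ResidueKey] | None = None,
    interface_cutoff: float = tables.INTERFACE_CUTOFF,
    ligand_cutoff: float = tables.LIGAND_CONTACT_CUTOFF,
    exposure_threshold: float = tables.EXPOSURE_THRESHOLD,
    druggability_threshold: float = tables.DRUGGABILITY_THRESHOLD,
    sasa_points: int = 960,
) -> dict[ResidueKey, ResidueAnnotation]:
    """Compute the full per-residue annotation table for one structure."""
    sasa = compute_sasa(structure, n_points=sasa_points)
    interface = interface_residues(structure, interface_cutoff)
    contacts = ligand_contact_residues(structure, ligand_cutoff)
    binding = binding_residues(structure, pockets, contacts, druggability_threshold)
    catalytic = catalytic or set()
    did3 = did3 or set()

    out: dict[ResidueKey, ResidueAnnotation] = {}
    for chain in structure.polymer_chains():
        for res in chain.polymer_residues():
            pct, exposed = sidechain_exposure(
                structure, res, sasa, threshold=exposure_threshold
            )
            out[res.key] = ResidueAnnotation(
                key=res.key,
                aa=res.aa,
                exposure_pct=pct,
                exposed=exposed,
                interface=res.key in interface,
                did3=res.key in did3,
                binding=res.key in binding,
                catalytic=res.key in catalytic,
                rel_bfactor=relative_bfactor(structure, res),
            )
    return out


def write_annotation_tsv(
    annotations: dict[ResidueKey, ResidueAnnotation],
    path: str | Path,
    structure_id: str = "",
) -> None:
    """One row per residue: every flag and value, tab-separated."""
    cols = [
        "structure_id", "chain", "resnum", "icode", "aa", "exposure_pct",
        "exposed", "interface", "did3", "binding", "catalytic", "rel_bfactor",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for key in sorted(annotations):
            a = annotations[key]
            pct = "" if a.exposure_pct is None else f"{a.exposure_pct:.2f}"
            exposed = "" if a.exposed is None else str(a.exposed).lower()
            fh.write(
                "\t".join(
                    [
                        structure_id, key[0], str(key[1]), key[2], a.aa, pct,
                        exposed, str(a.interface).lower(), str(a.did3).lower(),
                        str(a.binding).lower(), str(a.catalytic).lower(),
                        f"{a.rel_bfactor:.3f}",
                    ]
                )
                + "\n"
            )
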