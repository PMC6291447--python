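"""Folding free-energy change (ddG) ingestion and thresholding.

ddG (kcal/mol) is mutant minus wild-type folding free energy, computed by
an external empirical force-field program; this package ingests its
output rather than re-deriving the energy function. Two dialects are
read: the BuildModel difference table (``Dif_*.fxout``-style, one row per
mutation with the energy difference in the first numeric column) and
paired Stability outputs (one total energy per file, wt and mutant).

Variants without any ddG are not discarded: the diagnosis stage treats
them as not-high and flags the result as stability-unknown.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import tables
from .errors import FileParseError

__all__ = [
    "StabilityRecord",
    "parse_foldx_output",
    "write_foldx_dif",
    "parse_stability_energy",
    "record_from_stability_pair",
    "high_ddg",
]

#: BuildModel mutation tag: wt aa, chain id, residue number, mutant aa,
#: optional trailing semicolon — e.g. ``GA12V;``.
_MUTATION_TAG = re.compile(r"^([A-Z])([A-Za-z0-9])(-?\d+)([A-Z]);?$")


@dataclass(frozen=True)
class StabilityRecord:
    """One mutation's energies on one structure (kcal/mol)."""

    wt_aa: str
    position: int
    mut_aa: str
    chain_id: str
    structure_id: str
    wt_energy: float
    mut_energy: float

    @property
    def ddg(self) -> float:
        return self.mut_energy - self.wt_energy

    @property
    def variant_key(self) -> tuple[str, int, str]:
        return (self.wt_aa, self.position, self.mut_aa)


def parse_foldx_output(path: str | Path, structure_id: str = "") -> list[StabilityRecord]:
    """Parse a BuildModel difference table.

    Rows are ``TAG<TAB>ddG[<TAB>...]``; header/comment lines (starting
    with ``#`` or not matching a mutation tag in the first column, e.g. a
    program banner) are skipped only before the first data row. Malformed
    rows after that point raise :class:`FileParseError` with the line
    number. An empty file yields an empty list.
    """
    records: list[StabilityRecord] = []
    seen_data = False
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        m = _MUTATION_TAG.match(fields[0].strip())
        if m is None:
            if seen_data:
                raise FileParseError(f"line {line_no}: bad mutation tag {fields[0]!r}")
            continue  # banner / header line
        seen_data = True
        if len(fields) < 2:
            raise FileParseError(f"line {line_no}: missing energy column")
        try:
            ddg = float(fields[1])
        except ValueError:
            raise FileParseError(f"line {line_no}: bad energy value {fields[1]!r}")
        records.append(
            StabilityRecord(
                wt_aa=m.group(1),
                chain_id=m.group(2),
                position=int(m.group(3)),
                mut_aa=m.group(4),
                structure_id=structure_id,
                wt_energy=0.0,
                mut_energy=ddg,
            )
        )
    return records


def write_foldx_dif(records: list[StabilityRecord], path: str | Path) -> None:
    """Write records back in the BuildModel difference dialect."""
    with open(path, "w") as fh:
        for rec in records:
            tag = f"{rec.wt_aa}{rec.chain_id}{rec.position}{rec.mut_aa};"
            fh.write(f"{tag}\t{rec.ddg:.6g}\n")


def parse_stability_energy(path: str | Path) -> float:
    """Total energy (kcal/mol) from a Stability-dialect file: the first
    numeric column of the first data row."""
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        for field in line.split("\t"):
            try:
                return float(field)
            except ValueError:
                continue
    raise FileParseError(f"{path}: no numeric energy found")


def record_from_stability_pair(
    wt_path: str | Path,
    mut_path: str | Path,
    wt_aa: str,
    position: int,
    mut_aa: str,
    chain_id: str = "A",
    structure_id: str = "",
) -> StabilityRecord:
    """Build a record from paired wild-type/mutant Stability outputs;
    ddG = mutant energy - wild-type energy."""
    return StabilityRecord(
        wt_aa=wt_aa,
        position=position,
        mut_aa=mut_aa,
        chain_id=chain_id,
        structure_id=structure_id,
        wt_energy=parse_stability_energy(wt_path),
        mut_energy=parse_stability_energy(mut_path),
    )


def high_ddg(ddg: float, threshold: float = tables.DDG_THRESHOLD) -> bool:
    """Strictly-greater-than rule: mutations with ddG above ``threshold``
    (default 2 kcal/mol) carry a high destabilisation flag; exactly at the
    threshold does not."""
    return ddg > threshold
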