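"""Sequence-level per-residue scores.

Three quantities feed the pipeline from the sequence side:

* **Conservation** in bits from a protein-family alignment: the
  sequence-logo letter height of the wild-type residue, ``p(aa) * IC``
  with ``IC = log2(20) - H`` over the column's gap-free frequencies.
  Positions outside the family-assigned region are reported as
  not-assigned (``None``) rather than zero.
* **Aggregation propensity**: either ingested from an external
  per-residue score file (first-class path, e.g. output of a dedicated
  aggregation predictor) or computed by a documented surrogate — the max
  over sliding windows containing the residue of the mean of a bundled
  0-1 propensity scale.
* **Switch propensity** (alpha-helix to beta-sheet): external file, or a
  surrogate that flags mutations which move a helix-favouring window's
  sheet-minus-helix propensity balance beyond a threshold.

Every surrogate is a pure function of (sequence, tables, thresholds); the
``source`` field of each profile records which path produced it, and the
diagnosis report carries that provenance through.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import AlignIO

from . import tables
from .errors import FileParseError
from .model import Variant

__all__ = [
    "AlignmentColumn",
    "PropensityProfile",
    "read_msa_columns",
    "column_information",
    "conservation_score",
    "aggregation_profile",
    "read_score_file",
    "high_aggregability",
    "high_switchability",
    "MAX_INFORMATION_BITS",
]

MAX_INFORMATION_BITS = math.log2(20.0)


@dataclass
class AlignmentColumn:
    """Gap-free residue counts of one alignment column."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_effective(self) -> int:
        return sum(self.counts.values())

    def frequency(self, aa: str) -> float:
        n = self.n_effective
        return self.counts.get(aa, 0) / n if n else 0.0


def column_information(col: AlignmentColumn) -> float:
    """Information content in bits: ``log2(20) - H`` with Shannon entropy H
    over the column's gap-free amino-acid frequencies. Bounded in
    ``[0, log2 20]``; an all-gap column is undefined and raises."""
    n = col.n_effective
    if n == 0:
        raise ValueError("column has no non-gap residues")
    entropy = 0.0
    for count in col.counts.values():
        if count:
            p = count / n
            entropy -= p * math.log2(p)
    return max(MAX_INFORMATION_BITS - entropy, 0.0)


def read_msa_columns(
    path: str | Path,
    fmt: Optional[str] = None,
    reference_id: Optional[str] = None,
    ref_start: int = 1,
) -> tuple[list[AlignmentColumn], dict[int, int]]:
    """Read an MSA (FASTA or Stockholm) into columns plus a position map.

    The reference row (first row, or the one whose id matches
    ``reference_id``) defines which alignment columns are assigned to
    which reference positions: its non-gap characters advance the
    reference position starting at ``ref_start``. Returns
    ``(columns, ref_position -> column index)``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in (".sto", ".stk", ".stockholm") else "fasta"
    msa = AlignIO.read(str(path), fmt)
    if len(msa) == 0:
        raise FileParseError(f"{path}: empty alignment")
    ref_row = msa[0]
    if reference_id is not None:
        matches = [rec for rec in msa if rec.id == reference_id]
        if not matches:
            raise FileParseError(f"{path}: no row with id {reference_id!r}")
        ref_row = matches[0]

    n_cols = msa.get_alignment_length()
    columns = [AlignmentColumn() for _ in range(n_cols)]
    for rec in msa:
        for ci, ch in enumerate(str(rec.seq).upper()):
            if ch in tables.STANDARD_AA1:
                columns[ci].counts[ch] = columns[ci].counts.get(ch, 0) + 1

    colmap: dict[int, int] = {}
    pos = ref_start
    for ci, ch in enumerate(str(ref_row.seq).upper()):
        if ch in tables.STANDARD_AA1:
            colmap[pos] = ci
            pos += 1
    return columns, colmap


def conservation_score(
    columns: Sequence[AlignmentColumn],
    colmap: dict[int, int],
    ref_position: int,
    wt_aa: str,
) -> Optional[float]:
    """Sequence-logo letter height (bits) of the wild-type residue at a
    reference position, or ``None`` when the position is not assigned to
    any alignment column."""
    if wt_aa not in tables.STANDARD_AA1:
        raise ValueError(f"not a standard amino acid: {wt_aa!r}")
    ci = colmap.get(ref_position)
    if ci is None:
        return None
    col = columns[ci]
    if col.n_effective == 0:
        return None
    return col.frequency(wt_aa) * column_information(col)


# --- propensity profiles ----------------------------------------------------

@dataclass
class PropensityProfile:
    """Per-residue propensity scores, 1-based access via :meth:`at`."""

    scores: list[float]
    source: str = "surrogate"  # "surrogate" | "external_file"

    def at(self, position: int) -> float:
        if not 1 <= position <= len(self.scores):
            raise IndexError(
                f"position {position} outside profile of length {len(self.scores)}"
            )
        return self.scores[position - 1]

    def __len__(self) -> int:
        return len(self.scores)


def aggregation_profile(
    seq: str,
    window: int = 5,
    scale: dict[str, float] = tables.AGGREGATION_SCALE,
) -> PropensityProfile:
    """Surrogate aggregation propensity: each residue scores the maximum,
    over all length-``window`` windows containing it, of the window's mean
    scale value. Sequences shorter than the window score their global
    mean everywhere."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    vals = [scale[aa] for aa in seq.upper()]
    n = len(vals)
    if n == 0:
        return PropensityProfile([])
    if n < window:
        mean = sum(vals) / n
        return PropensityProfile([mean] * n)
    window_means = [
        sum(vals[s : s + window]) / window for s in range(n - window + 1)
    ]
    scores = []
    for i in range(n):
        lo = max(0, i - window + 1)
        hi = min(i, n - window)
        scores.append(max(window_means[lo : hi + 1]))
    return PropensityProfile(scores)


def read_score_file(path: str | Path) -> PropensityProfile:
    """Ingest an external per-residue score TSV (``position<TAB>score``,
    1-based contiguous positions). Takes precedence over the surrogate."""
    pairs: list[tuple[int, float]] = []
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.lower().startswith("position"):
            continue
        fields = line.split("\t")
        try:
            pairs.append((int(fields[0]), float(fields[1])))
        except (IndexError, ValueError):
            raise FileParseError(f"line {line_no}: expected 'position<TAB>score'")
    pairs.sort()
    if pairs and [p for p, _ in pairs] != list(range(pairs[0][0], pairs[0][0] + len(pairs))):
        raise FileParseError("positions must be contiguous")
    return PropensityProfile([s for _, s in pairs], source="external_file")


def high_aggregability(
    profile_wt: PropensityProfile,
    profile_mut: PropensityProfile,
    residue_pos: int,
    delta_threshold: float = tables.AGGREGATION_DELTA,
) -> bool:
    """Flag when the mutation raises the site's aggregation propensity by
    strictly more than ``delta_threshold``."""
    if len(profile_wt) != len(profile_mut):
        raise ValueError("wt and mutant profiles differ in length")
    return profile_mut.at(residue_pos) - profile_wt.at(residue_pos) > delta_threshold


def high_switchability(
    seq: str,
    variant: Variant,
    window: int = 5,
    delta_threshold: float = tables.SWITCH_DELTA,
    helix: dict[str, float] = tables.HELIX_PROPENSITY,
    sheet: dict[str, float] = tables.SHEET_PROPENSITY,
    external_positions: Optional[set[int]] = None,
) -> bool:
    """Flag mutations prone to switch a helix-favouring context to sheet.

    Surrogate rule: over the window centred on the site (clipped at the
    sequence ends), the wild-type context must favour helix (mean helix
    propensity > mean sheet propensity) and the mutation must raise the
    window's sheet-minus-helix balance by strictly more than
    ``delta_threshold``. If ``external_positions`` (from a per-residue
    switch-prone file) is supplied it overrides the surrogate entirely.
    """
    pos = variant.position
    if not 1 <= pos <= len(seq):
        raise IndexError(f"position {pos} outside sequence of length {len(seq)}")
    if seq[pos - 1].upper() != variant.wt_aa:
        raise ValueError(
            f"sequence has {seq[pos - 1]} at {pos}, variant expects {variant.wt_aa}"
        )
    if external_positions is not None:
        return pos in external_positions

    half = window // 2
    lo = max(0, pos - 1 - half)
    hi = min(len(seq), pos + half)
    wt_win = seq[lo:hi].upper()
    mut_win = (seq[: pos - 1] + variant.mut_aa + seq[pos:])[lo:hi].upper()

    def balance(win: str) -> tuple[float, float]:
        h = sum(helix[a] for a in win) / len(win)
        s = sum(sheet[a] for a in win) / len(win)
        return h, s

    wt_h, wt_s = balance(wt_win)
    mut_h, mut_s = balance(mut_win)
    helix_favouring = wt_h > wt_s
    delta = (mut_s - mut_h) - (wt_s - wt_h)
    return helix_favouring and delta > delta_threshold
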