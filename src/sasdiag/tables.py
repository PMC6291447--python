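"""Bundled parameter tables.

Every table here is a plain module-level constant so users can inspect,
copy and override it; functions that consume a table accept it as an
argument with the constant as default.
"""

from __future__ import annotations

# --- amino acid alphabets -------------------------------------------------

AA3_TO_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in AA3_TO_AA1.items()}
STANDARD_AA1 = frozenset(AA1_TO_AA3)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# --- het-group classification ---------------------------------------------

#: Codes treated as solvent/buffer/cryoprotectant and therefore never able
#: to confer a binding label. Monoatomic ions are solvent by default; edit
#: or pass your own set to change that. Loadable from a one-code-per-line
#: file via :func:`sasdiag.structure_io.load_solvent_list`.
DEFAULT_SOLVENT_CODES = frozenset({
    # water
    "HOH", "DOD", "WAT", "H2O",
    # buffers / cryoprotectants / additives
    "SO4", "PO4", "GOL", "EDO", "PEG", "PG4", "PGE", "ACT", "DMS",
    "MPD", "TRS", "EPE", "MES", "FMT", "NO3", "ACY", "BME",
    # monoatomic ions
    "CL", "NA", "K", "MG", "CA", "ZN", "MN", "BR", "IOD", "F",
    "CS", "LI", "CD", "NI", "CU", "CO", "FE", "FE2", "HG", "SR", "BA",
})

# --- van der Waals radii (Å) ----------------------------------------------

#: Bondi-style radii keyed by upper-case element symbol. Elements missing
#: from this table raise a configuration error during SASA computation.
VDW_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "B": 1.92, "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "MN": 2.05,
    "FE": 2.05, "ZN": 1.39, "CU": 1.40, "NI": 1.63, "CO": 2.00, "CD": 1.58,
    "HG": 1.55, "LI": 1.82, "CS": 3.43, "SR": 2.49, "BA": 2.68,
}

# --- reference maximal sidechain SASA (Å², Gly-X-Gly context) -------------

#: Denominator of the sidechain exposure percentage. Glycine has no
#: sidechain and is never assigned an exposure. Values follow the classic
#: extended Gly-X-Gly tripeptide reference.
MAX_SIDECHAIN_SASA = {
    "A": 67.0, "R": 196.0, "N": 113.0, "D": 106.0, "C": 104.0,
    "E": 138.0, "Q": 144.0, "H": 151.0, "I": 140.0, "L": 137.0,
    "K": 167.0, "M": 160.0, "F": 175.0, "P": 105.0, "S": 80.0,
    "T": 102.0, "W": 217.0, "Y": 187.0, "V": 117.0,
}

# --- sequence propensity scales -------------------------------------------

#: Normalised 0-1 beta-aggregation propensity surrogate scale: a blend of
#: hydrophobicity and beta-sheet preference. Only relative order matters;
#: the diagnosis consumes a thresholded delta, not absolute values.
AGGREGATION_SCALE = {
    "A": 0.30, "C": 0.70, "D": 0.05, "E": 0.05, "F": 0.90,
    "G": 0.10, "H": 0.30, "I": 0.95, "K": 0.05, "L": 0.85,
    "M": 0.70, "N": 0.15, "P": 0.00, "Q": 0.20, "R": 0.10,
    "S": 0.25, "T": 0.35, "V": 1.00, "W": 0.80, "Y": 0.75,
}

#: Chou-Fasman alpha-helix propensities.
HELIX_PROPENSITY = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13,
    "G": 0.57, "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21,
    "M": 1.45, "N": 0.67, "P": 0.57, "Q": 1.11, "R": 0.98,
    "S": 0.77, "T": 0.83, "V": 1.06, "W": 1.08, "Y": 0.69,
}

#: Chou-Fasman beta-sheet propensities.
SHEET_PROPENSITY = {
    "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38,
    "G": 0.75, "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30,
    "M": 1.05, "N": 0.89, "P": 0.55, "Q": 1.10, "R": 0.93,
    "S": 0.75, "T": 1.19, "V": 1.70, "W": 1.37, "Y": 1.47,
}

# --- default thresholds ----------------------------------------------------

DDG_THRESHOLD = 2.0          #: kcal/mol; strictly greater => "High ddG variation"
EXPOSURE_THRESHOLD = 50.0    #: percent; strictly greater => exposed
INTERFACE_CUTOFF = 5.0       #: Å; strictly less => interface contact
LIGAND_CONTACT_CUTOFF = 5.0  #: Å; strictly less => ligand contact
DRUGGABILITY_THRESHOLD = 0.5 #: pocket score; strictly greater => binding pocket
MIN_COVERAGE = 20            #: residues; structures below are discarded
AGGREGATION_DELTA = 0.2      #: surrogate score delta; strictly greater => flag
SWITCH_DELTA = 0.2           #: surrogate propensity delta; strictly greater => flag
IDENTITY_FLOOR = 0.95        #: minimum sequence identity for a usable mapping
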