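"""Shared residue/nucleotide chemistry tables.

Centralizes the atom-name vocabularies, van der Waals radii, reference
accessibilities and background amino-acid frequencies used across the
feature modules, so that every cutoff and reference value lives in one
place and can be retuned.
"""

from __future__ import annotations

# Canonical amino-acid ordering (PSI-BLAST column order is different; see
# PSSM_AA_ORDER below).
AA_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

# Deoxyribonucleotide residue names (PDB v3) -> one-letter code.
DNA_3TO1 = {"DA": "A", "DC": "C", "DG": "G", "DT": "T", "DI": "I"}
RNA_NAMES = {"A", "C", "G", "U", "I"}

# PSI-BLAST ASCII PSSM column order.
PSSM_AA_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")

# Protein backbone heavy-atom and hydrogen names; everything else is sidechain.
PROTEIN_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
PROTEIN_BACKBONE_H = {"H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT"}

# Nucleotide subunit atom classes: phosphate, sugar (primed names), nucleobase.
PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P"}


def protein_atom_class(name: str) -> str:
    if name in PROTEIN_BACKBONE_ATOMS or name in PROTEIN_BACKBONE_H:
        return "backbone"
    return "sidechain"


def nucleic_atom_class(name: str) -> str:
    if name in PHOSPHATE_ATOMS:
        return "phosphate"
    if name.endswith("'"):
        return "sugar"
    return "nucleobase"


# Element van der Waals radii (A), NACCESS-flavoured united-heavy-atom values.
VDW_RADII = {
    "C": 1.80,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

# Theoretical maximum ASA of residue X in an extended Ala-X-Ala tripeptide
# (Tien et al. 2013, theoretical values), A^2. Used as the RSA denominator
# for the `total` atom category.
MAX_ASA_TOTAL = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Reference backbone ASA in the extended tripeptide; treated as
# residue-independent (glycine aside, backbone exposure varies little).
MAX_ASA_MAINCHAIN = 40.0

# Sidechain heavy-atom counts and the number of those that are polar
# (N/O/S), per residue type. Used to split the sidechain reference area
# into polar and nonpolar parts and to build toy sidechains.
SIDECHAIN_HEAVY_COUNT = {
    "A": 1, "R": 7, "N": 4, "D": 4, "C": 2, "Q": 5, "E": 5, "G": 0,
    "H": 6, "I": 4, "L": 4, "K": 5, "M": 4, "F": 7, "P": 3, "S": 2,
    "T": 3, "W": 10, "Y": 8, "V": 3,
}
SIDECHAIN_POLAR_COUNT = {
    "A": 0, "R": 3, "N": 2, "D": 2, "C": 1, "Q": 2, "E": 2, "G": 0,
    "H": 2, "I": 0, "L": 0, "K": 1, "M": 1, "F": 0, "P": 0, "S": 1,
    "T": 1, "W": 1, "Y": 1, "V": 0,
}

# BLOSUM62 background amino-acid frequencies (Capra & Singh's choice of
# background for divergence-based conservation), in AA_ORDER.
BLOSUM62_BACKGROUND = {
    "A": 0.078, "R": 0.051, "N": 0.041, "D": 0.052, "C": 0.024,
    "Q": 0.034, "E": 0.059, "G": 0.083, "H": 0.025, "I": 0.062,
    "L": 0.092, "K": 0.056, "M": 0.024, "F": 0.044, "P": 0.043,
    "S": 0.059, "T": 0.055, "W": 0.014, "Y": 0.034, "V": 0.072,
}

# Heuristic protein-nucleic-acid interface propensities (log-odds flavoured,
# positive = enriched at interfaces). Built-in values for the default
# knowledge-score provider; external providers may replace them.
INTERFACE_PROPENSITY = {
    "R": 0.90, "K": 0.80, "H": 0.50, "S": 0.30, "T": 0.30,
    "N": 0.40, "Q": 0.30, "Y": 0.40, "W": 0.20, "G": 0.10,
    "A": -0.20, "D": -0.10, "E": -0.20, "C": -0.30, "F": -0.10,
    "I": -0.50, "L": -0.50, "M": -0.30, "P": -0.10, "V": -0.50,
}
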