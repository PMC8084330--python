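"""Geometric-partition energy features from per-residue-pair decompositions.

A molecular-mechanics/GBSA binding free energy decomposed at the residue-pair
level supplies, for every unordered monomer pair (including self entries),
five terms: the total and its electrostatic, van der Waals, polar-solvation
and nonpolar-solvation components. This module reads such tables and
aggregates them into five feature groups:

* ``EWC``  - energies of the whole complex (1 partition);
* ``ETOR`` - energies between the target residue and other protein residues
  split by distance shell: 0 (the self entry), (0,3], (3,4], (4,5],
  (5,6], (6,inf) A (6 partitions);
* ``EPP``  - sums of per-residue energies over the same shells (6);
* ``EINI`` - pair-energy sums over the interface vs everything else (2);
* ``EPI``  - the interface sum split into residue-residue,
  residue-nucleotide and nucleotide-nucleotide pairs (3).

Each feature block carries wild-type values and mutant-minus-wild-type
differences, five terms per partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .structure_io import (
    ComplexStructure,
    InterfaceSet,
    MonomerKey,
    MutationRecord,
    detect_interface,
    min_heavy_distance,
)

log = logging.getLogger(__name__)

TERMS = ("total", "ele", "vdw", "gb", "sa")
N_TERMS = 5

GB_MODELS = ("HCT", "OBC1", "OBC2", "GBn1", "GBn2", "synthetic")

#: (low, high] distance-shell boundaries for ETOR/EPP; shell 0 is the self entry.
SHELL_EDGES = ((0.0, 3.0), (3.0, 4.0), (4.0, 5.0), (5.0, 6.0), (6.0, np.inf))
SHELL_LABELS = ("0", "0-3", "3-4", "4-5", "5-6", ">6")

GROUP_PARTITIONS = {
    "EWC": ("whole",),
    "ETOR": SHELL_LABELS,
    "EPP": SHELL_LABELS,
    "EINI": ("interface", "noninterface"),
    "EPI": ("res-res", "res-nuc", "nuc-nuc"),
}
ENERGY_GROUPS = tuple(GROUP_PARTITIONS)


class EnergyTerms(NamedTuple):
    """Five-term energy record (kcal/mol)."""

    total: float
    ele: float
    vdw: float
    gb: float
    sa: float

    @classmethod
    def from_array(cls, a) -> "EnergyTerms":
        return cls(*(float(x) for x in np.asarray(a, dtype=float)))

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


class EnergyTableError(ValueError):
    pass


def shell_index(distance: float) -> int:
    """Distance shell (1..5) for a positive inter-residue distance."""
    if distance <= 0:
        raise ValueError("shell_index expects a positive distance")
    for i, (lo, hi) in enumerate(SHELL_EDGES, start=1):
        if lo < distance <= hi:
            return i
    raise AssertionError("unreachable")


@dataclass
class PairEnergyTable:
    """Per-residue-pair 5-term decomposition for one complex state.

    ``entries`` maps canonical unordered pairs (ordered by monomer position
    in the bound structure) to term arrays of shape (5,).
    """

    complex_id: str
    state: str  # wild_type | mutant
    gb_model_tag: str
    entries: dict[tuple[MonomerKey, MonomerKey], np.ndarray]

    def pair(self, a: MonomerKey, b: MonomerKey) -> Optional[np.ndarray]:
        return self.entries.get((a, b)) if (a, b) in self.entries else self.entries.get((b, a))

    def self_entry(self, key: MonomerKey) -> np.ndarray:
        e = self.entries.get((key, key))
        if e is None:
            raise EnergyTableError(f"{self.complex_id}: missing self entry for {key}")
        return e

    def pairs_involving(self, key: MonomerKey):
        for (a, b), terms in self.entries.items():
            if a == b:
                continue
            if a == key or b == key:
                yield (a, b), terms


def read_pair_energy_table(
    path,
    structure: ComplexStructure,
    state: str = "wild_type",
    gb_model_tag: str = "synthetic",
    closure_tol: Optional[float] = 1e-3,
) -> PairEnergyTable:
    """Read a decomposition CSV and canonicalize it against ``structure``.

    Dialect: header ``chain_i,seq_i,icode_i,chain_j,seq_j,icode_j,
    total,ele,vdw,gb,sa``; one row per unordered pair or per direction
    (directional duplicates are summed); units kcal/mol.
    """
    df = pd.read_csv(path, dtype={"chain_i": str, "chain_j": str,
                                  "icode_i": str, "icode_j": str})
    needed = ["chain_i", "seq_i", "icode_i", "chain_j", "seq_j", "icode_j", *TERMS]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise EnergyTableError(f"{path}: missing columns {missing}")

    def key_of(row, side: str, idx: int) -> MonomerKey:
        icode = row[f"icode_{side}"]
        icode = "" if (icode is None or (isinstance(icode, float) and np.isnan(icode))) else str(icode).strip()
        k = MonomerKey(str(row[f"chain_{side}"]).strip(), int(row[f"seq_{side}"]), icode)
        if k not in structure:
            raise EnergyTableError(f"{path} row {idx}: monomer {k} not in structure")
        return k

    entries: dict[tuple[MonomerKey, MonomerKey], np.ndarray] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        rowd = row._asdict()
        ki = key_of(rowd, "i", idx)
        kj = key_of(rowd, "j", idx)
        if structure.index(ki) > structure.index(kj):
            ki, kj = kj, ki
        terms = np.array([float(rowd[t]) for t in TERMS])
        if not np.all(np.isfinite(terms)):
            raise EnergyTableError(f"{path} row {idx}: non-finite energy terms")
        prev = entries.get((ki, kj))
        entries[(ki, kj)] = terms if prev is None else prev + terms

    for key in structure.keys():
        if (key, key) not in entries:
            raise EnergyTableError(f"{path}: missing self entry for monomer {key}")

    if closure_tol is not None:
        for (a, b), t in entries.items():
            gap = abs(t[0] - t[1:].sum())
            if gap > closure_tol:
                raise EnergyTableError(
                    f"{path}: pair ({a},{b}) violates term closure by {gap:.3g} kcal/mol"
                )
    return PairEnergyTable(
        complex_id=structure.id, state=state, gb_model_tag=gb_model_tag, entries=entries
    )


# ---------------------------------------------------------------------------
# aggregations
# ---------------------------------------------------------------------------

def ewc(table: PairEnergyTable) -> EnergyTerms:
    """Whole-complex energies: term-wise sum over all entries."""
    if not table.entries:
        raise EnergyTableError("empty energy table")
    return EnergyTerms.from_array(sum(table.entries.values()))


def _require_protein_target(structure: ComplexStructure, target: MonomerKey) -> None:
    if not structure.is_protein(target):
        raise EnergyTableError(f"target {target} is not a protein residue")


def _protein_shells(structure: ComplexStructure, target: MonomerKey) -> dict[MonomerKey, int]:
    t = structure.monomer(target)
    out = {}
    for o in structure.protein_monomers:
        if o.key == target:
            continue
        out[o.key] = shell_index(min_heavy_distance(t, o))
    return out


def etor(table: PairEnergyTable, structure: ComplexStructure, target: MonomerKey) -> np.ndarray:
    """Target-vs-other-residue pair energies by distance shell; shape (6, 5).

    Shell 0 holds the target's decomposition self entry; shells 1..5 sum
    the target-other pairwise energies over protein residues in each shell.
    """
    _require_protein_target(structure, target)
    out = np.zeros((6, N_TERMS))
    out[0] = table.self_entry(target)
    for key, shell in _protein_shells(structure, target).items():
        pe = table.pair(target, key)
        if pe is not None:
            out[shell] += pe
    return out


def residue_energy(table: PairEnergyTable, key: MonomerKey) -> np.ndarray:
    """Total interaction energy of one monomer: self entry plus all its pairs."""
    out = table.self_entry(key).copy()
    for _, terms in table.pairs_involving(key):
        out += terms
    return out


def epp(table: PairEnergyTable, structure: ComplexStructure, target: MonomerKey) -> np.ndarray:
    """Partitioned-protein residue-energy sums by shell; shape (6, 5)."""
    _require_protein_target(structure, target)
    out = np.zeros((6, N_TERMS))
    out[0] = residue_energy(table, target)
    for key, shell in _protein_shells(structure, target).items():
        out[shell] += residue_energy(table, key)
    return out


def _interface_members(iface: InterfaceSet) -> frozenset:
    return iface.members


def eini(table: PairEnergyTable, iface: InterfaceSet) -> np.ndarray:
    """Interface vs noninterface pair-energy sums; shape (2, 5).

    The interface partition covers all pairwise combinations (and self
    entries) among interface residues and nucleotides; every remaining
    entry goes to the noninterface partition.
    """
    members = _interface_members(iface)
    if not members:
        log.warning("empty interface: interface partition is all-zero")
    out = np.zeros((2, N_TERMS))
    for (a, b), terms in table.entries.items():
        if a in members and b in members:
            out[0] += terms
        else:
            out[1] += terms
    return out


def epi(table: PairEnergyTable, structure: ComplexStructure, iface: InterfaceSet) -> np.ndarray:
    """Interface pair energies split by pair kind; shape (3, 5).

    Rows: residue-residue, residue-nucleotide, nucleotide-nucleotide. Self
    entries join the same-kind partition.
    """
    members = _interface_members(iface)
    if not members:
        log.warning("empty interface: all partitions zero")
    out = np.zeros((3, N_TERMS))
    for (a, b), terms in table.entries.items():
        if not (a in members and b in members):
            continue
        n_protein = int(structure.is_protein(a)) + int(structure.is_protein(b))
        out[2 - n_protein] += terms
    return out


# ---------------------------------------------------------------------------
# feature blocks
# ---------------------------------------------------------------------------

@dataclass
class EnergyFeatureBlock:
    """One energy feature group: wild-type values plus mutant differences."""

    group: str
    labels: tuple
    wt: np.ndarray  # (partitions, 5)
    diff: np.ndarray  # (partitions, 5), mutant - wild-type

    def __post_init__(self) -> None:
        expected = (len(GROUP_PARTITIONS[self.group]), N_TERMS)
        if self.wt.shape != expected or self.diff.shape != expected:
            raise ValueError(f"{self.group}: expected value shape {expected}")

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.wt.ravel(), self.diff.ravel()])

    def __len__(self) -> int:
        return 2 * self.wt.size


def energy_group_values(
    table: PairEnergyTable,
    structure: ComplexStructure,
    target: MonomerKey,
    iface: InterfaceSet,
) -> dict[str, np.ndarray]:
    """All five raw group matrices for one state."""
    return {
        "EWC": ewc(table).as_array().reshape(1, N_TERMS),
        "ETOR": etor(table, structure, target),
        "EPP": epp(table, structure, target),
        "EINI": eini(table, iface),
        "EPI": epi(table, structure, iface),
    }


def assemble_energy_block(
    wt_table: PairEnergyTable,
    mut_table: PairEnergyTable,
    structure_wt: ComplexStructure,
    structure_mut: ComplexStructure,
    mutation: MutationRecord,
    iface: Optional[InterfaceSet] = None,
    cutoff: float = 5.0,
) -> dict[str, EnergyFeatureBlock]:
    """Five energy feature blocks (wild-type values and mut-wt differences).

    Interface membership defaults to the wild-type structure's interface and
    is reused for the mutant-state partitions; the target key is the mutated
    position in both states.
    """
    if wt_table.gb_model_tag != mut_table.gb_model_tag:
        raise EnergyTableError(
            f"GB model mismatch: {wt_table.gb_model_tag} vs {mut_table.gb_model_tag}"
        )
    if mutation.monomer_key is None:
        raise ValueError("mutation must be bound to the structure first")
    if iface is None:
        iface = detect_interface(structure_wt, cutoff=cutoff)
    target = mutation.monomer_key
    wt_vals = energy_group_values(wt_table, structure_wt, target, iface)
    mut_vals = energy_group_values(mut_table, structure_mut, target, iface)
    return {
        g: EnergyFeatureBlock(
            group=g,
            labels=GROUP_PARTITIONS[g],
            wt=wt_vals[g],
            diff=mut_vals[g] - wt_vals[g],
        )
        for g in ENERGY_GROUPS
    }
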