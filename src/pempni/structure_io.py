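"""Complex structures, interfaces and mutation records.

Reads one protein-nucleic-acid complex from a PDB file into a light
in-memory model (chains typed as protein/DNA/RNA), computes inter-monomer
heavy-atom geometry, detects the binding interface under the 5 A contact
rule, classifies residue locations in the Levy scheme, and validates
mutation records against the structure.

Conventions
-----------
* Author numbering throughout; a monomer is keyed by
  ``(chain_id, seq_id, icode)``.
* Inter-monomer distance is the minimum over heavy-atom pairs.
* The interface uses a *strict* ``< cutoff`` comparison (default 5.0 A).
* Waters, ions and other HETATM ligands are dropped on read; hydrogens are
  kept but flagged and excluded from all geometry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from ._chemdata import (
    AA_3TO1,
    DNA_3TO1,
    RNA_NAMES,
    nucleic_atom_class,
    protein_atom_class,
)


class StructureError(ValueError):
    """Unreadable or internally inconsistent structure input."""


class ChainTypingError(StructureError):
    """A chain mixes amino acids and nucleotides (or DNA and RNA)."""


class MutationBindingError(ValueError):
    """A mutation record cannot be matched to the structure."""


class MonomerKey(NamedTuple):
    """Identifier of one residue/nucleotide: chain, author seq id, icode."""

    chain: str
    seq: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A:52" or "A:52A"
        return f"{self.chain}:{self.seq}{self.icode}"


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    is_heavy: bool
    record_class: str  # backbone|sidechain or phosphate|sugar|nucleobase

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Monomer:
    chain_id: str
    seq_id: int
    icode: str
    kind: str  # amino_acid | dna_nucleotide | rna_nucleotide
    code: str  # one-letter code
    atoms: list[Atom]
    _heavy_coords: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def key(self) -> MonomerKey:
        return MonomerKey(self.chain_id, self.seq_id, self.icode)

    @property
    def is_protein(self) -> bool:
        return self.kind == "amino_acid"

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    @property
    def heavy_coords(self) -> np.ndarray:
        if self._heavy_coords is None:
            heavy = self.heavy_atoms
            if not heavy:
                raise StructureError(f"monomer {self.key} has no heavy atoms")
            self._heavy_coords = np.vstack([a.coords for a in heavy])
        return self._heavy_coords


@dataclass
class ComplexStructure:
    """One protein-nucleic-acid complex: ordered monomers plus chain typing."""

    id: str
    monomers: list[Monomer]
    chain_types: dict[str, str]  # chain_id -> protein | DNA | RNA

    def __post_init__(self) -> None:
        self._index: dict[MonomerKey, int] = {}
        for i, m in enumerate(self.monomers):
            if m.key in self._index:
                raise StructureError(f"duplicate monomer key {m.key}")
            self._index[m.key] = i

    # -- lookup ---------------------------------------------------------
    def __contains__(self, key: MonomerKey) -> bool:
        return key in self._index

    def index(self, key: MonomerKey) -> int:
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"monomer {key} not in structure {self.id}") from None

    def monomer(self, key: MonomerKey) -> Monomer:
        return self.monomers[self.index(key)]

    def keys(self) -> list[MonomerKey]:
        return [m.key for m in self.monomers]

    def is_protein(self, key: MonomerKey) -> bool:
        return self.monomer(key).is_protein

    # -- selections -----------------------------------------------------
    @property
    def protein_monomers(self) -> list[Monomer]:
        return [m for m in self.monomers if m.is_protein]

    @property
    def nucleic_monomers(self) -> list[Monomer]:
        return [m for m in self.monomers if not m.is_protein]

    @property
    def has_protein(self) -> bool:
        return any(t == "protein" for t in self.chain_types.values())

    @property
    def has_nucleic(self) -> bool:
        return any(t in ("DNA", "RNA") for t in self.chain_types.values())

    def require_complex(self) -> None:
        if not (self.has_protein and self.has_nucleic):
            raise StructureError(
                f"structure {self.id} needs >=1 protein and >=1 nucleic-acid chain "
                f"for complex-level operations (chains: {self.chain_types})"
            )

    def protein_only(self) -> "ComplexStructure":
        """Unbound protein state: protein chains extracted in place."""
        chains = {c: t for c, t in self.chain_types.items() if t == "protein"}
        monos = [m for m in self.monomers if m.chain_id in chains]
        return ComplexStructure(id=f"{self.id}|protein", monomers=monos, chain_types=chains)


@dataclass(frozen=True)
class InterfaceSet:
    """Residue-nucleotide contacts under a heavy-atom distance cutoff."""

    contact_pairs: frozenset
    interface_residues: frozenset
    interface_nucleotides: frozenset
    cutoff: float

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple], cutoff: float) -> "InterfaceSet":
        pairs = frozenset(pairs)
        return cls(
            contact_pairs=pairs,
            interface_residues=frozenset(p[0] for p in pairs),
            interface_nucleotides=frozenset(p[1] for p in pairs),
            cutoff=float(cutoff),
        )

    @property
    def members(self) -> frozenset:
        return self.interface_residues | self.interface_nucleotides


@dataclass(frozen=True)
class MutationRecord:
    complex_id: str
    chain_id: str
    position: int
    wt_code: str
    mut_code: str
    icode: str = ""
    ddg_exp: Optional[float] = None
    monomer_key: Optional[MonomerKey] = None

    def __post_init__(self) -> None:
        if self.wt_code == self.mut_code:
            raise ValueError(
                f"{self.complex_id} {self.chain_id}:{self.position}: "
                f"wild-type and mutant codes are identical ({self.wt_code})"
            )

    @property
    def label(self) -> str:
        return (
            f"{self.complex_id}:{self.chain_id}:{self.position}{self.icode}:"
            f"{self.wt_code}>{self.mut_code}"
        )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _monomer_kind(resname: str) -> Optional[tuple[str, str]]:
    """(kind, one-letter code) for a residue name, or None if unrecognized."""
    if resname in AA_3TO1:
        return "amino_acid", AA_3TO1[resname]
    if resname in DNA_3TO1:
        return "dna_nucleotide", DNA_3TO1[resname]
    if resname in RNA_NAMES:
        return "rna_nucleotide", resname
    return None


_KIND_TO_CHAIN = {"amino_acid": "protein", "dna_nucleotide": "DNA", "rna_nucleotide": "RNA"}


def read_structure(path, structure_id: Optional[str] = None) -> ComplexStructure:
    """Read the first model of a PDB file into a :class:`ComplexStructure`.

    Hydrogens are retained (``is_heavy=False``); waters, ions and other
    HETATM ligands are dropped; for alternate locations the
    highest-occupancy conformer is kept. Chains are typed from the residue
    vocabulary; a chain mixing monomer kinds raises
    :class:`ChainTypingError`.
    """
    from Bio.PDB import PDBParser  # deferred: import cost

    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure(structure_id or "complex", str(path))
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    try:
        model = next(iter(bio))
    except StopIteration:
        raise StructureError(f"PDB file {path} contains no model") from None

    monomers: list[Monomer] = []
    chain_types: dict[str, str] = {}
    for chain in model:
        for res in chain:
            hetfield, seq_id, icode = res.id
            if hetfield.strip():  # waters, ions, ligands
                continue
            resname = res.get_resname().strip()
            kc = _monomer_kind(resname)
            if kc is None:
                raise StructureError(
                    f"unrecognized monomer {resname} at {chain.id}:{seq_id} in {path}"
                )
            kind, code = kc
            ctype = _KIND_TO_CHAIN[kind]
            prev = chain_types.get(chain.id)
            if prev is not None and prev != ctype:
                raise ChainTypingError(
                    f"chain {chain.id} mixes {prev} and {ctype} monomers"
                )
            chain_types[chain.id] = ctype
            atoms = []
            for atom in res:  # disordered atoms yield highest-occupancy child
                name = atom.get_name()
                element = (atom.element or "").strip().upper()
                if not element:
                    element = re.sub(r"[^A-Z]", "", name.upper())[:1]
                cls = (
                    protein_atom_class(name)
                    if kind == "amino_acid"
                    else nucleic_atom_class(name)
                )
                atoms.append(
                    Atom(
                        name=name,
                        element=element,
                        coords=atom.get_coord(),
                        is_heavy=element not in ("H", "D"),
                        record_class=cls,
                    )
                )
            mono = Monomer(
                chain_id=chain.id,
                seq_id=int(seq_id),
                icode=icode.strip(),
                kind=kind,
                code=code,
                atoms=atoms,
            )
            if not mono.heavy_atoms:
                raise StructureError(f"monomer {mono.key} has no heavy atoms")
            monomers.append(mono)

    if not monomers:
        raise StructureError(f"no polymer monomers found in {path}")
    return ComplexStructure(
        id=structure_id or str(path), monomers=monomers, chain_types=chain_types
    )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def min_heavy_distance(a: Monomer, b: Monomer) -> float:
    """Minimum Euclidean distance over heavy-atom pairs of two monomers."""
    return float(cdist(a.heavy_coords, b.heavy_coords).min())


def detect_interface(c: ComplexStructure, cutoff: float = 5.0) -> InterfaceSet:
    """All (residue, nucleotide) pairs with min heavy-atom distance < cutoff.

    A KD-tree prunes candidate pairs; every candidate is confirmed with the
    exact pairwise minimum so the result equals the all-pairs scan.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    c.require_complex()
    prot = c.protein_monomers
    nuc = c.nucleic_monomers

    def atom_table(monos):
        coords = np.vstack([m.heavy_coords for m in monos])
        owner = np.concatenate(
            [np.full(len(m.heavy_coords), i) for i, m in enumerate(monos)]
        )
        return coords, owner

    pc, po = atom_table(prot)
    nc, no = atom_table(nuc)
    tree_p, tree_n = cKDTree(pc), cKDTree(nc)
    candidates = set()
    for ip, neigh in enumerate(tree_p.query_ball_tree(tree_n, r=cutoff)):
        for jn in neigh:
            candidates.add((int(po[ip]), int(no[jn])))
    pairs = []
    for i, j in candidates:
        if min_heavy_distance(prot[i], nuc[j]) < cutoff:  # strict, per the rule
            pairs.append((prot[i].key, nuc[j].key))
    return InterfaceSet.from_pairs(pairs, cutoff)


# ---------------------------------------------------------------------------
# Levy geometric locations
# ---------------------------------------------------------------------------

#: rASA exposure threshold (%) separating buried from exposed residues.
LEVY_EXPOSURE_CUTOFF = 25.0
#: below this, the change in rASA upon binding counts as zero.
LEVY_DRSA_EPS = 1e-6

LOCATION_CLASSES = ("interior", "surface", "support", "rim", "core")


def classify_location(
    u_rsa: float,
    b_rsa: float,
    exposure_cutoff: float = LEVY_EXPOSURE_CUTOFF,
    eps: float = LEVY_DRSA_EPS,
) -> str:
    """Five-class Levy location from unbound/bound relative accessibility (%).

    interior: buried, untouched by binding; surface: exposed, untouched;
    support: buried, loses area; rim: exposed in both states, loses area;
    core: exposed when unbound, buried in the complex.
    """
    d_rsa = u_rsa - b_rsa
    exposed_u = u_rsa >= exposure_cutoff
    if d_rsa <= eps:
        return "surface" if exposed_u else "interior"
    if not exposed_u:
        return "support"
    return "rim" if b_rsa >= exposure_cutoff else "core"


# ---------------------------------------------------------------------------
# mutation records
# ---------------------------------------------------------------------------

def bind_mutation(m: MutationRecord, c: ComplexStructure) -> MutationRecord:
    """Resolve a mutation against the structure, enforcing the wild-type code.

    Mirrors the elimination rule used during data curation: records whose
    stated wild-type residue does not match the structure are rejected.
    """
    key = MonomerKey(m.chain_id, m.position, m.icode)
    if key not in c:
        raise MutationBindingError(f"{m.label}: position {key} not found in {c.id}")
    mono = c.monomer(key)
    if not mono.is_protein:
        raise MutationBindingError(f"{m.label}: monomer {key} is not an amino acid")
    if mono.code != m.wt_code:
        raise MutationBindingError(
            f"{m.label}: wild-type code mismatch (structure has {mono.code} at {key})"
        )
    return replace(m, monomer_key=key)


def bind_mutations(
    records: Iterable[MutationRecord], c: ComplexStructure
) -> tuple[list[MutationRecord], list[tuple[MutationRecord, str]]]:
    """Batch binding: (bound records, [(rejected record, reason), ...])."""
    bound, rejected = [], []
    for rec in records:
        try:
            bound.append(bind_mutation(rec, c))
        except MutationBindingError as exc:
            rejected.append((rec, str(exc)))
    return bound, rejected


_POSITION_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")


def _parse_position(text) -> tuple[int, str]:
    m = _POSITION_RE.match(str(text).strip())
    if not m:
        raise ValueError(f"cannot parse residue position {text!r}")
    return int(m.group(1)), m.group(2).upper()


def read_mutation_table(path) -> list[MutationRecord]:
    """Read the mutation TSV: ``complex_id chain position wt mut ddg_exp``.

    ``ddg_exp`` (kcal/mol) is optional; positions may carry insertion codes
    (e.g. ``52A``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["complex_id", "chain", "position", "wt", "mut"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table {path} lacks columns: {missing}")
    records = []
    for _, row in df.iterrows():
        pos, icode = _parse_position(row["position"])
        ddg = None
        if "ddg_exp" in df.columns and pd.notna(row.get("ddg_exp")) and str(row["ddg_exp"]).strip():
            ddg = float(row["ddg_exp"])
        records.append(
            MutationRecord(
                complex_id=str(row["complex_id"]),
                chain_id=str(row["chain"]),
                position=pos,
                icode=icode,
                wt_code=str(row["wt"]).strip().upper(),
                mut_code=str(row["mut"]).strip().upper(),
                ddg_exp=ddg,
            )
        )
    return records


def write_mutation_table(records: Iterable[MutationRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "complex_id": r.complex_id,
                "chain": r.chain_id,
                "position": f"{r.position}{r.icode}",
                "wt": r.wt_code,
                "mut": r.mut_code,
                "ddg_exp": "" if r.ddg_exp is None else f"{r.ddg_exp:.6f}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
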