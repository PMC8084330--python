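"""Synthetic complexes, energy tables, profiles and datasets with planted signal.

Every pipeline stage consumes real file formats (PDB, decomposition CSV,
ASCII PSSM, mutation TSV). This module generates small but structurally
valid instances of all four so that the full feature/model stack can be
exercised - and its statistical behaviour verified against planted truth -
without an external energy engine.

The toy geometry is an idealized straight peptide (backbone plus labelled
sidechain pseudo-atoms, sized per residue type) laid against an idealized
straight nucleic strand so that a configured subset of residues falls
within the 5 A contact rule. Pair energies are drawn from a
distance-decaying kernel with exact five-term closure; the mutant table
perturbs the mutated residue's pairs by a planted per-mutation effect, and
the regression label is a linear function of that effect plus Gaussian
noise. Generation is fully reproducible from the spec seed (byte-identical
files).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from ._chemdata import (
    AA_1TO3,
    AA_ORDER,
    PSSM_AA_ORDER,
    SIDECHAIN_HEAVY_COUNT,
    SIDECHAIN_POLAR_COUNT,
    nucleic_atom_class,
    protein_atom_class,
)
from .energy_features import TERMS, PairEnergyTable
from .modeling import Dataset
from .structure_io import (
    Atom,
    ComplexStructure,
    Monomer,
    MonomerKey,
    MutationRecord,
    bind_mutation,
    detect_interface,
    write_mutation_table,
)


class SyntheticSpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Generation parameters; the defaults define the benchmark conditions."""

    seed: int = 2021
    n_complexes: int = 40
    mutations_per_complex: int = 6
    nucleic_kind: str = "DNA"  # DNA | RNA
    n_residues: int = 12
    n_nucleotides: int = 6
    n_interface_residues: int = 4
    noise_sigma: float = 0.3  # kcal/mol, label noise
    effect_low: float = -1.0  # planted per-mutation energy effect range
    effect_high: float = 4.0
    effect_weight: float = 1.0  # ddG slope on the planted effect
    residue_spacing: float = 4.5  # A along the strand axis
    interface_gap: float = 4.0  # A between paired residue and nucleotide
    noninterface_gap: float = 12.0

    def validate(self) -> None:
        if self.noise_sigma < 0:
            raise SyntheticSpecError("noise_sigma must be >= 0")
        if self.n_complexes < 1 or self.mutations_per_complex < 1:
            raise SyntheticSpecError("need at least one complex and one mutation")
        if self.nucleic_kind not in ("DNA", "RNA"):
            raise SyntheticSpecError("nucleic_kind must be DNA or RNA")
        if not 1 <= self.n_interface_residues <= min(self.n_residues, self.n_nucleotides):
            raise SyntheticSpecError(
                "n_interface_residues must fit within residues and nucleotides"
            )
        if self.mutations_per_complex > self.n_residues:
            raise SyntheticSpecError("more mutations than residues in a complex")
        if self.interface_gap >= 5.0 or self.noninterface_gap <= 6.0:
            raise SyntheticSpecError(
                "interface_gap must be < 5 and noninterface_gap > 6 for the contact rule"
            )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# toy geometry
# ---------------------------------------------------------------------------

_CARBON_NAMES = ("CB", "CG", "CD", "CE", "CZ", "CH", "CG1", "CD1", "CE1", "CZ1")
_POLAR_NAMES = ("ND1", "NE2", "NH1", "OD1")
_DNA_CODES = ("A", "C", "G", "T")
_RNA_CODES = ("A", "C", "G", "U")


def _sidechain_atoms(code: str, x: float) -> list[Atom]:
    n_total = SIDECHAIN_HEAVY_COUNT[code]
    n_polar = SIDECHAIN_POLAR_COUNT[code]
    names = list(_CARBON_NAMES[: n_total - n_polar]) + list(_POLAR_NAMES[:n_polar])
    atoms = []
    for j, name in enumerate(names):
        pos = np.round([x + 0.25 * (j % 2), -1.4 - 0.8 * j, 0.7], 3)
        atoms.append(Atom(name=name, element=name[0], coords=pos,
                          is_heavy=True, record_class="sidechain"))
    return atoms


def _residue(code: str, seq_id: int, x: float) -> Monomer:
    backbone = [
        ("N", "N", (x - 1.2, 0.4, 0.0)),
        ("CA", "C", (x, 0.0, 0.0)),
        ("C", "C", (x + 1.2, 0.4, 0.0)),
        ("O", "O", (x + 1.2, 1.6, 0.0)),
    ]
    atoms = [
        Atom(name=n, element=e, coords=np.round(c, 3), is_heavy=True,
             record_class=protein_atom_class(n))
        for n, e, c in backbone
    ]
    atoms.extend(_sidechain_atoms(code, x))
    return Monomer(chain_id="A", seq_id=seq_id, icode="", kind="amino_acid",
                   code=code, atoms=atoms)


_NUCLEOTIDE_TEMPLATE = (
    # name, offsets relative to (x, 0, z0); z offsets all >= 0
    ("N9", (0.0, 0.0, 0.0)),
    ("C8", (0.7, 0.3, 0.6)),
    ("N7", (0.9, -0.4, 1.3)),
    ("O6", (-0.8, 0.5, 1.6)),
    ("C1'", (0.0, 0.9, 1.2)),
    ("O4'", (-0.6, 1.5, 1.8)),
    ("C4'", (0.4, 1.9, 2.3)),
    ("P", (0.0, 2.6, 3.1)),
    ("OP1", (-0.8, 3.2, 3.4)),
    ("OP2", (0.8, 3.2, 3.4)),
)


def _nucleotide(code: str, kind: str, seq_id: int, x: float, z0: float) -> Monomer:
    atoms = []
    for name, (dx, dy, dz) in _NUCLEOTIDE_TEMPLATE:
        atoms.append(
            Atom(name=name, element=name[0], coords=np.round([x + dx, dy, z0 + dz], 3),
                 is_heavy=True, record_class=nucleic_atom_class(name))
        )
    return Monomer(chain_id="B", seq_id=seq_id, icode="", kind=kind, code=code, atoms=atoms)


@dataclass
class ToyMutation:
    record: MutationRecord  # bound to the wild-type structure
    mut_structure: ComplexStructure
    wt_table: PairEnergyTable
    mut_table: PairEnergyTable
    effect: float  # planted whole-complex total-energy change


@dataclass
class ToyComplex:
    cid: str
    wt_structure: ComplexStructure
    interface_keys: tuple  # designated interface residue keys
    profile_probs: np.ndarray  # (n_residues, 20) in AA_ORDER
    mutations: list[ToyMutation] = field(default_factory=list)


def make_toy_complex(spec: SyntheticSpec, cid: str, rng: np.random.Generator) -> ToyComplex:
    """Wild-type toy complex with designated interface residues."""
    spec.validate()
    codes = [str(rng.choice(AA_ORDER)) for _ in range(spec.n_residues)]
    residues = [
        _residue(codes[i], i + 1, i * spec.residue_spacing) for i in range(spec.n_residues)
    ]
    iface_idx = sorted(
        set(np.linspace(0, spec.n_residues - 1, spec.n_interface_residues).round().astype(int))
    )
    kind = "dna_nucleotide" if spec.nucleic_kind == "DNA" else "rna_nucleotide"
    pool = _DNA_CODES if spec.nucleic_kind == "DNA" else _RNA_CODES
    nucs = []
    z_near = 0.7 + spec.interface_gap
    z_far = 0.7 + spec.noninterface_gap
    for j in range(spec.n_nucleotides):
        code = str(rng.choice(pool))
        if j < len(iface_idx):
            x = iface_idx[j] * spec.residue_spacing
            z0 = z_near
        else:  # park the rest beyond the protein end, in the far plane
            x = (spec.n_residues + 1 + j) * spec.residue_spacing
            z0 = z_far
        nucs.append(_nucleotide(code, kind, j + 1, x, z0))
    structure = ComplexStructure(
        id=cid, monomers=residues + nucs,
        chain_types={"A": "protein", "B": spec.nucleic_kind},
    )
    _check_sterics(structure)
    iface_keys = tuple(residues[i].key for i in iface_idx)
    probs = _make_profile_probs(codes, iface_idx, rng)
    return ToyComplex(cid=cid, wt_structure=structure, interface_keys=iface_keys,
                      profile_probs=probs)


def _check_sterics(structure: ComplexStructure, min_gap: float = 0.5) -> None:
    from .structure_io import min_heavy_distance

    for r in structure.protein_monomers:
        for n in structure.nucleic_monomers:
            if min_heavy_distance(r, n) < min_gap:
                raise SyntheticSpecError(
                    f"steric coincidence between {r.key} and {n.key} (< {min_gap} A)"
                )


def mutate_structure(
    wt: ComplexStructure, target: MonomerKey, mut_code: str
) -> ComplexStructure:
    """Mutant structure: same geometry, mutated sidechain composition."""
    monomers = []
    for m in wt.monomers:
        if m.key == target:
            backbone = [a for a in m.atoms if a.record_class != "sidechain"]
            x = next(a for a in backbone if a.name == "CA").coords[0]
            monomers.append(
                Monomer(chain_id=m.chain_id, seq_id=m.seq_id, icode=m.icode,
                        kind=m.kind, code=mut_code,
                        atoms=backbone + _sidechain_atoms(mut_code, float(x)))
            )
        else:
            monomers.append(m)
    return ComplexStructure(id=f"{wt.id}|{target}{mut_code}", monomers=monomers,
                            chain_types=dict(wt.chain_types))


# ---------------------------------------------------------------------------
# energy tables
# ---------------------------------------------------------------------------

def draw_wt_table(
    structure: ComplexStructure,
    rng: np.random.Generator,
    kernel_scale: float = 3.0,
    term_sd: float = 0.6,
) -> tuple[PairEnergyTable, dict]:
    """Wild-type decomposition table from a distance-decaying kernel.

    Pair terms decay with inter-monomer distance; closure (total = sum of
    the four components) is exact by construction. Also returns the kernel
    weights, reused when planting mutant effects.
    """
    from .structure_io import min_heavy_distance

    monomers = structure.monomers
    entries: dict[tuple[MonomerKey, MonomerKey], np.ndarray] = {}
    kernels: dict[tuple[MonomerKey, MonomerKey], float] = {}
    for i, a in enumerate(monomers):
        for j in range(i, len(monomers)):
            b = monomers[j]
            k = 1.0 if i == j else float(np.exp(-min_heavy_distance(a, b) / kernel_scale))
            comps = rng.normal(0.0, term_sd, size=4) * k
            terms = np.concatenate([[comps.sum()], comps])
            entries[(a.key, b.key)] = terms
            kernels[(a.key, b.key)] = k
    wt = PairEnergyTable(complex_id=structure.id, state="wild_type",
                         gb_model_tag="synthetic", entries=entries)
    return wt, kernels


def apply_planted_effect(
    wt: PairEnergyTable, kernels: dict, target: MonomerKey, effect: float
) -> PairEnergyTable:
    """Mutant table: ``effect`` added to the electrostatic term of the
    target's entries, split in proportion to the distance kernel, so the
    whole-complex total changes by exactly ``effect``."""
    target_pairs = [p for p in wt.entries if target in p]
    weights = np.array([kernels[p] for p in target_pairs])
    weights = weights / weights.sum()
    mut_entries = {p: t.copy() for p, t in wt.entries.items()}
    for p, w in zip(target_pairs, weights):
        delta = effect * w
        mut_entries[p][0] += delta  # total
        mut_entries[p][1] += delta  # ele
    return PairEnergyTable(complex_id=wt.complex_id, state="mutant",
                           gb_model_tag="synthetic", entries=mut_entries)


def make_pair_energy_tables(
    toy: ToyComplex,
    target: MonomerKey,
    effect: float,
    rng: np.random.Generator,
    kernel_scale: float = 3.0,
    term_sd: float = 0.6,
) -> tuple[PairEnergyTable, PairEnergyTable]:
    """Convenience: freshly drawn wild-type table plus its planted mutant."""
    wt, kernels = draw_wt_table(toy.wt_structure, rng, kernel_scale, term_sd)
    return wt, apply_planted_effect(wt, kernels, target, effect)


# ---------------------------------------------------------------------------
# conservation profiles
# ---------------------------------------------------------------------------

def _make_profile_probs(codes, conserved_idx, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet rows, sharpened at designated conserved positions."""
    probs = rng.dirichlet(np.full(20, 0.8), size=len(codes))
    for i in conserved_idx:
        row = np.full(20, 0.01)
        row[AA_ORDER.index(codes[i])] = 1.0 - 0.01 * 19
        probs[i] = row
    return probs


# ---------------------------------------------------------------------------
# full datasets
# ---------------------------------------------------------------------------

def generate(spec: SyntheticSpec) -> list[ToyComplex]:
    """All toy complexes with mutations, tables and planted effects."""
    spec.validate()
    complexes = []
    for ci in range(spec.n_complexes):
        rng = np.random.default_rng([spec.seed % (2**31), ci])
        cid = f"SYN{ci:03d}"
        toy = make_toy_complex(spec, cid, rng)
        wt_table, kernels = draw_wt_table(toy.wt_structure, rng)
        codes = {m.key: m.code for m in toy.wt_structure.protein_monomers}
        iface = list(toy.interface_keys)
        others = [k for k in codes if k not in toy.interface_keys]
        order = iface + [others[i] for i in rng.permutation(len(others))]
        positions = order[: spec.mutations_per_complex]
        for mi, key in enumerate(positions):
            wt_code = codes[key]
            mut_code = str(rng.choice([a for a in AA_ORDER if a != wt_code]))
            effect = float(rng.uniform(spec.effect_low, spec.effect_high))
            noise = float(rng.normal(0.0, spec.noise_sigma)) if spec.noise_sigma else 0.0
            ddg = spec.effect_weight * effect + noise
            record = bind_mutation(
                MutationRecord(complex_id=cid, chain_id=key.chain, position=key.seq,
                               icode=key.icode, wt_code=wt_code, mut_code=mut_code,
                               ddg_exp=round(ddg, 6)),
                toy.wt_structure,
            )
            mut_structure = mutate_structure(toy.wt_structure, key, mut_code)
            mut_table = apply_planted_effect(wt_table, kernels, key, effect)
            toy.mutations.append(
                ToyMutation(record=record, mut_structure=mut_structure,
                            wt_table=wt_table, mut_table=mut_table, effect=effect)
            )
        complexes.append(toy)
    return complexes


# -- serialization ----------------------------------------------------------

def structure_to_pdb(structure: ComplexStructure) -> str:
    lines = []
    serial = 0
    last_chain = None
    for m in structure.monomers:
        if last_chain is not None and m.chain_id != last_chain:
            lines.append("TER")
        last_chain = m.chain_id
        if m.kind == "amino_acid":
            resname = AA_1TO3[m.code]
        elif m.kind == "dna_nucleotide":
            resname = f"D{m.code}"
        else:
            resname = m.code
        for a in m.atoms:
            serial += 1
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.coords
            lines.append(
                f"ATOM  {serial:5d} {name} {resname:>3s} {m.chain_id}"
                f"{m.seq_id:4d}{m.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def table_to_csv(table: PairEnergyTable) -> str:
    lines = ["chain_i,seq_i,icode_i,chain_j,seq_j,icode_j," + ",".join(TERMS)]
    for (a, b), t in table.entries.items():
        vals = ",".join(f"{v:.9f}" for v in t)
        lines.append(f"{a.chain},{a.seq},{a.icode},{b.chain},{b.seq},{b.icode},{vals}")
    return "\n".join(lines) + "\n"


def profile_to_pssm(codes, probs: np.ndarray) -> str:
    """ASCII PSSM text (PSI-BLAST layout, weighted observed percentages)."""
    head = [
        "",
        "Last position-specific scoring matrix computed, weighted observed"
        " percentages rounded down, information per position, and relative"
        " weight of gapless real matches to pseudocounts",
        "            " + "   ".join(PSSM_AA_ORDER) + "   " + "   ".join(PSSM_AA_ORDER),
    ]
    rows = []
    reorder = [AA_ORDER.index(a) for a in PSSM_AA_ORDER]
    for i, code in enumerate(codes):
        pct = np.floor(probs[i][reorder] * 100).astype(int)
        logodds = " ".join(f"{0:3d}" for _ in range(20))
        pcts = " ".join(f"{v:3d}" for v in pct)
        rows.append(f"{i + 1:5d} {code}  {logodds}  {pcts}  0.50 1.00")
    return "\n".join(head + rows) + "\n"


@dataclass
class SyntheticBundle:
    """Paths and planted truth of one generated dataset on disk."""

    root: Path
    spec: SyntheticSpec
    complex_ids: list

    @property
    def mutations_path(self) -> Path:
        return self.root / "mutations.tsv"

    def wt_pdb(self, cid: str) -> Path:
        return self.root / "structures" / f"{cid}_wt.pdb"

    def mut_pdb(self, cid: str, k: int) -> Path:
        return self.root / "structures" / f"{cid}_m{k}.pdb"

    def wt_table(self, cid: str) -> Path:
        return self.root / "tables" / f"{cid}_wt.csv"

    def mut_table(self, cid: str, k: int) -> Path:
        return self.root / "tables" / f"{cid}_m{k}.csv"

    def profile(self, cid: str) -> Path:
        return self.root / "profiles" / f"{cid}.pssm"

    @property
    def truth_path(self) -> Path:
        return self.root / "truth.json"


def make_dataset(spec: SyntheticSpec, outdir) -> SyntheticBundle:
    """Generate and write a complete dataset bundle (structures, tables,
    profiles, mutation TSV with ddG labels, and the planted-truth report)."""
    root = Path(outdir)
    for sub in ("structures", "tables", "profiles"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    complexes = generate(spec)
    bundle = SyntheticBundle(root=root, spec=spec, complex_ids=[c.cid for c in complexes])
    records = []
    truth = {"spec": spec.to_dict(), "mutations": []}
    for toy in complexes:
        bundle.wt_pdb(toy.cid).write_text(structure_to_pdb(toy.wt_structure))
        codes = [m.code for m in toy.wt_structure.protein_monomers]
        bundle.profile(toy.cid).write_text(profile_to_pssm(codes, toy.profile_probs))
        if toy.mutations:
            bundle.wt_table(toy.cid).write_text(table_to_csv(toy.mutations[0].wt_table))
        for k, tm in enumerate(toy.mutations):
            bundle.mut_pdb(toy.cid, k).write_text(structure_to_pdb(tm.mut_structure))
            bundle.mut_table(toy.cid, k).write_text(table_to_csv(tm.mut_table))
            records.append(tm.record)
            truth["mutations"].append(
                {"label": tm.record.label, "effect": tm.effect,
                 "ddg": tm.record.ddg_exp}
            )
    write_mutation_table(records, bundle.mutations_path)
    bundle.truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return bundle


# -- in-memory model dataset -------------------------------------------------

def build_energy_dataset(
    spec: SyntheticSpec, groups=("EWC",), cutoff: float = 5.0
) -> tuple[Dataset, dict]:
    """Feature dataset computed through the energy pipeline, without disk I/O.

    Returns the dataset (requested energy groups only) plus the planted
    truth (per-mutation effects).
    """
    from .energy_features import assemble_energy_block

    complexes = generate(spec)
    records, effects = [], []
    columns: dict[str, list] = {g: [] for g in groups}
    for toy in complexes:
        iface = detect_interface(toy.wt_structure, cutoff=cutoff)
        for tm in toy.mutations:
            blocks = assemble_energy_block(
                tm.wt_table, tm.mut_table, toy.wt_structure, tm.mut_structure,
                tm.record, iface=iface,
            )
            for g in groups:
                columns[g].append(blocks[g].vector)
            records.append(tm.record)
            effects.append(tm.effect)
    ds = Dataset(
        records=records,
        features={g: np.vstack(v) for g, v in columns.items()},
        ddg=np.array([r.ddg_exp for r in records]),
    )
    return ds, {"effects": np.array(effects), "spec": spec.to_dict()}


def add_noise_groups(ds: Dataset, names, dim: int, seed: int) -> Dataset:
    """Append pure-noise feature groups (for selection experiments)."""
    rng = np.random.default_rng(seed)
    extra = {name: rng.normal(size=(len(ds), dim)) for name in names}
    return ds.with_groups(extra)
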