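"""Shared construction helpers and brute-force oracles for the tests."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from pempni.structure_io import (
    Atom,
    ComplexStructure,
    InterfaceSet,
    Monomer,
    min_heavy_distance,
)


def make_monomer(chain, seq, coords, kind="amino_acid", code="A", names=None,
                 elements=None, icode=""):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    names = names or [f"X{i}" for i in range(len(coords))]
    elements = elements or ["C"] * len(coords)
    atoms = [
        Atom(name=n, element=e, coords=c, is_heavy=e not in ("H", "D"),
             record_class="sidechain" if kind == "amino_acid" else "nucleobase")
        for n, e, c in zip(names, elements, coords)
    ]
    return Monomer(chain_id=chain, seq_id=seq, icode=icode, kind=kind, code=code,
                   atoms=atoms)


def random_structure(rng, n_protein=5, n_nucleic=5, atoms_per=3, box=20.0,
                     sid="random"):
    """Random multi-atom monomers in a box, one protein and one nucleic chain."""
    monomers = []
    for i in range(n_protein):
        coords = rng.uniform(0, box, size=(atoms_per, 3))
        monomers.append(make_monomer("A", i + 1, coords))
    for j in range(n_nucleic):
        coords = rng.uniform(0, box, size=(atoms_per, 3))
        monomers.append(
            make_monomer("B", j + 1, coords, kind="dna_nucleotide", code="G")
        )
    return ComplexStructure(id=sid, monomers=monomers,
                            chain_types={"A": "protein", "B": "DNA"})


def brute_force_interface(structure, cutoff=5.0):
    """O(n^2) all-pairs interface scan (the independent oracle)."""
    pairs = set()
    for r in structure.protein_monomers:
        for n in structure.nucleic_monomers:
            if cdist(r.heavy_coords, n.heavy_coords).min() < cutoff:
                pairs.add((r.key, n.key))
    return pairs


def brute_force_contacts(structure, target, cutoff=5.0):
    """Double-loop atomic-contact tally: {CFAA: (n, avg), CFNA: (n, avg)}."""
    t = structure.monomer(target)
    out = {}
    for name, kind_protein in (("CFAA", True), ("CFNA", False)):
        partners, atoms = 0, 0
        for other in structure.monomers:
            if other.key == target or other.is_protein != kind_protein:
                continue
            n = int((cdist(t.heavy_coords, other.heavy_coords) < cutoff).sum())
            if n:
                partners += 1
                atoms += n
        out[name] = (partners, atoms / partners if partners else 0.0)
    return out


def manual_pair_table(structure, rng, scale=1.0):
    """Random 5-term table with exact closure over all canonical pairs."""
    from pempni.energy_features import PairEnergyTable

    monomers = structure.monomers
    entries = {}
    for i, a in enumerate(monomers):
        for j in range(i, len(monomers)):
            comps = rng.normal(0, scale, size=4)
            entries[(a.key, monomers[j].key)] = np.concatenate([[comps.sum()], comps])
    return PairEnergyTable(complex_id=structure.id, state="wild_type",
                           gb_model_tag="synthetic", entries=entries)
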