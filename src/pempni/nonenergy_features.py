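"""Structural and sequence feature groups for target residues and interfaces.

Seventeen feature groups are registered:

======================  ====  =============================================
group                   dim   meaning
======================  ====  =============================================
bASA/uASA/dASA          5     absolute accessible surface area of the target
                              residue in the bound/unbound state and their
                              difference, over five atom categories (total,
                              mainchain, sidechain, polar sidechain,
                              nonpolar sidechain), A^2
bRSA/uRSA/dRSA          5     the relative counterparts, %
IR-dASA / IR-dRSA       5     dASA/dRSA summed over interface residues
NHB / IR-NHB            1     hydrogen bonds between the target (each
                              interface residue) and the rest of the complex
CFAA / CFNA             2     contact strength vs amino-acid / nucleic-acid
                              partners: (#interacting monomers, atomic
                              contacts per interacting monomer)
IR-CFAA / IR-CFNA       2     the same, summed over interface residues
ENDES / IR-ENDES        7     knowledge-based scores from a pluggable
                              provider (built-in: sidechain, propensity and
                              conservation scores; the rest zero-filled)
JSD                     1     Jensen-Shannon-divergence conservation of the
                              mutated position
======================  ====  =============================================

Solvent accessibility is computed with a deterministic Shrake-Rupley
sampler (golden-spiral sphere points, probe 1.4 A, NACCESS-style radii);
the unbound state is the protein chains extracted in place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Protocol

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, jensenshannon

from ._chemdata import (
    AA_ORDER,
    BLOSUM62_BACKGROUND,
    INTERFACE_PROPENSITY,
    MAX_ASA_MAINCHAIN,
    MAX_ASA_TOTAL,
    PSSM_AA_ORDER,
    SIDECHAIN_HEAVY_COUNT,
    SIDECHAIN_POLAR_COUNT,
    VDW_RADII,
)
from .structure_io import ComplexStructure, InterfaceSet, MonomerKey, MutationRecord

ATOM_CATEGORIES = ("total", "mainchain", "sidechain", "polar_sidechain", "nonpolar_sidechain")
POLAR_ELEMENTS = {"N", "O", "S", "P"}

#: registered nonenergy feature groups -> per-state vector length
NONENERGY_GROUPS = {
    "bASA": 5, "uASA": 5, "dASA": 5, "bRSA": 5, "uRSA": 5, "dRSA": 5,
    "IR-dASA": 5, "IR-dRSA": 5,
    "NHB": 1, "IR-NHB": 1,
    "CFAA": 2, "CFNA": 2, "IR-CFAA": 2, "IR-CFNA": 2,
    "ENDES": 7, "IR-ENDES": 7,
    "JSD": 1,
}


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# solvent accessibility
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere points on a golden spiral (deterministic)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(
    structure: ComplexStructure, probe: float = 1.4, n_points: int = 960
) -> dict[MonomerKey, np.ndarray]:
    """Per-heavy-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    Returns one array per monomer, aligned with its heavy-atom order.
    Deterministic for fixed ``n_points``.
    """
    monos = structure.monomers
    coords, radii, owner = [], [], []
    unknown = []
    for mi, m in enumerate(monos):
        for a in m.heavy_atoms:
            r = VDW_RADII.get(a.element)
            if r is None:
                unknown.append(f"{m.key}/{a.name}({a.element})")
                continue
            coords.append(a.coords)
            radii.append(r)
            owner.append(mi)
    if unknown:
        raise FeatureError(f"no vdW radius for atoms: {', '.join(unknown)}")
    coords = np.asarray(coords)
    radii = np.asarray(radii) + probe
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        shell = coords[i] + radii[i] * pts
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
        if neigh:
            d = cdist(shell, coords[neigh])
            accessible = np.all(d >= radii[neigh], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * radii[i] ** 2
    out: dict[MonomerKey, np.ndarray] = {}
    owner = np.asarray(owner)
    for mi, m in enumerate(monos):
        out[m.key] = areas[owner == mi]
    return out


def _category_masks(mono) -> dict[str, np.ndarray]:
    heavy = mono.heavy_atoms
    side = np.array([a.record_class == "sidechain" for a in heavy])
    polar = np.array([a.element in POLAR_ELEMENTS for a in heavy])
    return {
        "total": np.ones(len(heavy), dtype=bool),
        "mainchain": ~side,
        "sidechain": side,
        "polar_sidechain": side & polar,
        "nonpolar_sidechain": side & ~polar,
    }


def reference_asa(code: str) -> np.ndarray:
    """Reference (maximum) ASA per atom category for one residue type, A^2.

    Total from the extended-tripeptide theoretical values; mainchain a
    residue-independent constant; sidechain the remainder, split between
    polar and nonpolar in proportion to the residue's polar/nonpolar
    sidechain heavy-atom counts. Categories with a zero reference (e.g.
    glycine sidechains) yield RSA 0 by convention.
    """
    total = MAX_ASA_TOTAL[code]
    side = max(total - MAX_ASA_MAINCHAIN, 0.0)
    n_side = SIDECHAIN_HEAVY_COUNT[code]
    n_pol = SIDECHAIN_POLAR_COUNT[code]
    polar = side * (n_pol / n_side) if n_side else 0.0
    side_eff = side if n_side else 0.0
    return np.array([total, MAX_ASA_MAINCHAIN, side_eff, polar, side_eff - polar])


@dataclass
class AccessibilityRecord:
    """Bound/unbound absolute and relative accessibility of one residue."""

    key: MonomerKey
    code: str
    b_asa: np.ndarray  # (5,) per atom category, A^2
    u_asa: np.ndarray

    @property
    def d_asa(self) -> np.ndarray:
        return self.u_asa - self.b_asa

    def _rsa(self, asa: np.ndarray) -> np.ndarray:
        ref = reference_asa(self.code)
        out = np.zeros(5)
        nz = ref > 0
        out[nz] = asa[nz] / ref[nz] * 100.0
        return out

    @property
    def b_rsa(self) -> np.ndarray:
        return self._rsa(self.b_asa)

    @property
    def u_rsa(self) -> np.ndarray:
        return self._rsa(self.u_asa)

    @property
    def d_rsa(self) -> np.ndarray:
        return self.u_rsa - self.b_rsa


def accessibility_records(
    structure: ComplexStructure, probe: float = 1.4, n_points: int = 960
) -> dict[MonomerKey, AccessibilityRecord]:
    """Per-protein-residue accessibility in the bound and unbound states."""
    bound = sasa(structure, probe=probe, n_points=n_points)
    unbound = sasa(structure.protein_only(), probe=probe, n_points=n_points)
    out = {}
    for m in structure.protein_monomers:
        masks = _category_masks(m)
        b = np.array([bound[m.key][masks[c]].sum() for c in ATOM_CATEGORIES])
        u = np.array([unbound[m.key][masks[c]].sum() for c in ATOM_CATEGORIES])
        out[m.key] = AccessibilityRecord(key=m.key, code=m.code, b_asa=b, u_asa=u)
    return out


def accessibility_features(
    records: dict[MonomerKey, AccessibilityRecord],
    target: MonomerKey,
    iface: InterfaceSet,
) -> dict[str, np.ndarray]:
    """Six target-residue accessibility groups plus IR-dASA and IR-dRSA."""
    if target not in records:
        raise FeatureError(f"no accessibility record for target {target}")
    rec = records[target]
    iface_recs = [records[k] for k in sorted(iface.interface_residues) if k in records]
    return {
        "bASA": rec.b_asa, "uASA": rec.u_asa, "dASA": rec.d_asa,
        "bRSA": rec.b_rsa, "uRSA": rec.u_rsa, "dRSA": rec.d_rsa,
        "IR-dASA": (np.sum([r.d_asa for r in iface_recs], axis=0)
                    if iface_recs else np.zeros(5)),
        "IR-dRSA": (np.sum([r.d_rsa for r in iface_recs], axis=0)
                    if iface_recs else np.zeros(5)),
    }


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

#: sidechain/sugar hydroxyl oxygens that can donate
DONOR_OXYGENS = {"OG", "OG1", "OH", "O2'", "O3'", "O5'"}
#: nucleobase ring nitrogens treated as acceptors
ACCEPTOR_RING_N = {"N1", "N3", "N7"}

HB_MAX_DA = 3.5  # donor-acceptor distance cutoff, A
HB_MIN_ANGLE = 90.0  # antecedent-donor-acceptor angle, degrees
_COVALENT_CUTOFF = 1.8  # heavy-atom bond length used to find the antecedent


def _donors(mono):
    for a in mono.heavy_atoms:
        if a.element == "N" or (a.element == "O" and a.name in DONOR_OXYGENS):
            yield a


def _acceptors(mono):
    for a in mono.heavy_atoms:
        if a.element == "O":
            yield a
        elif (
            a.element == "N"
            and a.record_class == "nucleobase"
            and a.name in ACCEPTOR_RING_N
        ):
            yield a


def _antecedent(mono, donor):
    best, best_d = None, _COVALENT_CUTOFF
    for a in mono.heavy_atoms:
        if a is donor:
            continue
        d = float(np.linalg.norm(a.coords - donor.coords))
        if d < best_d:
            best, best_d = a, d
    return best


def _is_hbond(donor_mono, donor, acceptor) -> bool:
    d = float(np.linalg.norm(donor.coords - acceptor.coords))
    if d > HB_MAX_DA or d < 1e-6:
        return False
    ante = _antecedent(donor_mono, donor)
    if ante is None:
        return True  # angle unresolvable: accept on distance alone
    v1 = ante.coords - donor.coords
    v2 = acceptor.coords - donor.coords
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    return angle >= HB_MIN_ANGLE


def hydrogen_bonds(structure: ComplexStructure, target: MonomerKey) -> int:
    """Geometric hydrogen bonds between the target and the rest of the complex.

    A deliberate approximation of HBPLUS defaults: donor-acceptor distance
    <= 3.5 A and antecedent-donor-acceptor angle >= 90 deg when the donor's
    bonded heavy atom is resolvable; hydrogens are not required.
    """
    t = structure.monomer(target)
    count = 0
    for other in structure.monomers:
        if other.key == target:
            continue
        for donor in _donors(t):
            for acc in _acceptors(other):
                count += _is_hbond(t, donor, acc)
        for donor in _donors(other):
            for acc in _acceptors(t):
                count += _is_hbond(other, donor, acc)
    return count


def interface_hydrogen_bonds(structure: ComplexStructure, iface: InterfaceSet) -> int:
    """Cumulative NHB over interface residues."""
    return sum(hydrogen_bonds(structure, k) for k in sorted(iface.interface_residues))


# ---------------------------------------------------------------------------
# contact features
# ---------------------------------------------------------------------------

def _atomic_contacts(a, b, cutoff: float) -> int:
    return int((cdist(a.heavy_coords, b.heavy_coords) < cutoff).sum())


def contact_features(
    structure: ComplexStructure, target: MonomerKey, cutoff: float = 5.0
) -> dict[str, np.ndarray]:
    """CFAA and CFNA for one target residue.

    Each is (residue-contact strength, average atomic contact strength):
    the number of interacting partner monomers of that kind, and atomic
    contacts divided by that number (0 with no partner). Heavy atoms at a
    strict ``< cutoff`` comparison, the same rule as interface detection.
    """
    t = structure.monomer(target)
    tallies = {"CFAA": [0, 0], "CFNA": [0, 0]}
    for other in structure.monomers:
        if other.key == target:
            continue
        n = _atomic_contacts(t, other, cutoff)
        if n:
            slot = tallies["CFAA" if other.is_protein else "CFNA"]
            slot[0] += 1
            slot[1] += n
    out = {}
    for name, (npart, natom) in tallies.items():
        out[name] = np.array([npart, natom / npart if npart else 0.0])
    return out


def interface_contact_features(
    structure: ComplexStructure, iface: InterfaceSet, cutoff: float = 5.0
) -> dict[str, np.ndarray]:
    """IR-CFAA / IR-CFNA: component-wise sums over interface residues."""
    out = {"IR-CFAA": np.zeros(2), "IR-CFNA": np.zeros(2)}
    for key in sorted(iface.interface_residues):
        cf = contact_features(structure, key, cutoff=cutoff)
        out["IR-CFAA"] += cf["CFAA"]
        out["IR-CFNA"] += cf["CFNA"]
    return out


# ---------------------------------------------------------------------------
# evolutionary conservation
# ---------------------------------------------------------------------------

def blosum_background() -> np.ndarray:
    bg = np.array([BLOSUM62_BACKGROUND[a] for a in AA_ORDER])
    return bg / bg.sum()


@dataclass
class ConservationProfile:
    """Per-position amino-acid distributions (weighted observed percentages)."""

    probs: np.ndarray  # (L, 20) in AA_ORDER, rows normalized
    sequence: str  # profile sequence, length L

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 20:
            raise FeatureError("profile must be (L, 20)")
        if len(self.sequence) != len(self.probs):
            raise FeatureError("profile sequence length mismatch")

    def __len__(self) -> int:
        return len(self.probs)

    def map_to_chain(
        self, structure: ComplexStructure, chain_id: str
    ) -> dict[MonomerKey, int]:
        """Map profile rows to chain residues by sequence order."""
        residues = [m for m in structure.protein_monomers if m.chain_id == chain_id]
        if len(residues) != len(self):
            raise FeatureError(
                f"profile length {len(self)} != chain {chain_id} length {len(residues)}"
            )
        return {m.key: i for i, m in enumerate(residues)}


def read_pssm(path) -> ConservationProfile:
    """Read a PSI-BLAST ASCII PSSM, keeping the weighted observed percentages.

    Rows of all-zero percentages are replaced by the background distribution.
    """
    rows, seq = [], []
    reorder = [PSSM_AA_ORDER.index(a) for a in AA_ORDER]
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 44 or not parts[0].lstrip("-").isdigit():
                continue
            if len(parts[1]) != 1 or not parts[1].isalpha():
                continue
            seq.append(parts[1].upper())
            vals = np.array([float(x) for x in parts[22:42]])
            rows.append(vals[reorder])
    if not rows:
        raise FeatureError(f"no profile rows found in {path}")
    probs = np.asarray(rows)
    bg = blosum_background()
    sums = probs.sum(axis=1)
    out = np.empty_like(probs)
    for i, s in enumerate(sums):
        out[i] = bg if s <= 0 else probs[i] / s
    return ConservationProfile(probs=out, sequence="".join(seq))


def jsd_conservation(
    profile: ConservationProfile, row: int, background: Optional[np.ndarray] = None
) -> float:
    """Jensen-Shannon divergence (base 2, mixture weight 1/2) of one position
    against the background distribution. In [0, 1]; higher = more conserved."""
    if not 0 <= row < len(profile):
        raise FeatureError(f"profile row {row} out of range (L={len(profile)})")
    q = blosum_background() if background is None else np.asarray(background, float)
    p = profile.probs[row]
    js = float(jensenshannon(p, q, base=2.0)) ** 2
    return float(np.clip(js, 0.0, 1.0))


# ---------------------------------------------------------------------------
# knowledge-based (ENDES-style) scores
# ---------------------------------------------------------------------------

N_ENDES = 7


class EndesProvider(Protocol):
    """Provider of the seven per-residue knowledge-based scores."""

    def scores(
        self,
        structure: ComplexStructure,
        target: MonomerKey,
        iface: InterfaceSet,
        profile_row: Optional[tuple[ConservationProfile, int]] = None,
    ) -> np.ndarray: ...


class ZeroEndesProvider:
    """Degenerate provider: seven zeros (keeps the pipeline runnable)."""

    def scores(self, structure, target, iface, profile_row=None) -> np.ndarray:
        return np.zeros(N_ENDES)


class DefaultEndesProvider:
    """Built-in provider for the three named scores; the rest zero-filled.

    Components: [sidechain score (fraction of heavy atoms in the sidechain),
    propensity score (interface propensity of the residue type),
    conservation score (JSD if a profile is supplied, else 0), 0, 0, 0, 0].
    """

    def scores(self, structure, target, iface, profile_row=None) -> np.ndarray:
        mono = structure.monomer(target)
        heavy = mono.heavy_atoms
        side = sum(a.record_class == "sidechain" for a in heavy)
        out = np.zeros(N_ENDES)
        out[0] = side / len(heavy)
        out[1] = INTERFACE_PROPENSITY[mono.code]
        if profile_row is not None:
            out[2] = jsd_conservation(*profile_row)
        return out


def endes_scores(
    provider,
    structure: ComplexStructure,
    target: MonomerKey,
    iface: InterfaceSet,
    profile_row: Optional[tuple[ConservationProfile, int]] = None,
) -> np.ndarray:
    """Seven-score vector for the target residue, via the registered provider."""
    if provider is None:
        raise FeatureError(
            "no knowledge-score provider registered; configure a provider "
            "(DefaultEndesProvider gives the built-in scores)"
        )
    vec = np.asarray(provider.scores(structure, target, iface, profile_row), dtype=float)
    if vec.shape != (N_ENDES,):
        raise FeatureError(f"provider returned shape {vec.shape}, expected ({N_ENDES},)")
    return vec


def interface_endes_scores(
    provider,
    structure: ComplexStructure,
    iface: InterfaceSet,
    profile_map: Optional[dict[MonomerKey, tuple[ConservationProfile, int]]] = None,
) -> np.ndarray:
    """IR-ENDES: component-wise sum of provider scores over interface residues."""
    out = np.zeros(N_ENDES)
    for key in sorted(iface.interface_residues):
        pr = profile_map.get(key) if profile_map else None
        out += endes_scores(provider, structure, key, iface, pr)
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class NonEnergyFeatureBlock:
    group: str
    wt: np.ndarray
    diff: np.ndarray

    def __post_init__(self) -> None:
        n = NONENERGY_GROUPS[self.group]
        self.wt = np.atleast_1d(np.asarray(self.wt, dtype=float))
        self.diff = np.atleast_1d(np.asarray(self.diff, dtype=float))
        if self.wt.shape != (n,) or self.diff.shape != (n,):
            raise ValueError(f"{self.group}: expected vectors of length {n}")

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.wt, self.diff])

    def __len__(self) -> int:
        return 2 * len(self.wt)


def state_nonenergy_values(
    structure: ComplexStructure,
    target: MonomerKey,
    iface: InterfaceSet,
    profile: Optional[ConservationProfile] = None,
    provider=None,
    groups=None,
    cutoff: float = 5.0,
    probe: float = 1.4,
    n_points: int = 960,
) -> dict[str, np.ndarray]:
    """Raw per-state values for the requested nonenergy groups."""
    groups = tuple(NONENERGY_GROUPS) if groups is None else tuple(groups)
    unknown = [g for g in groups if g not in NONENERGY_GROUPS]
    if unknown:
        raise FeatureError(f"unknown feature groups: {unknown}")
    out: dict[str, np.ndarray] = {}

    asa_groups = {"bASA", "uASA", "dASA", "bRSA", "uRSA", "dRSA", "IR-dASA", "IR-dRSA"}
    if asa_groups & set(groups):
        recs = accessibility_records(structure, probe=probe, n_points=n_points)
        acc = accessibility_features(recs, target, iface)
        for g in asa_groups & set(groups):
            out[g] = acc[g]
    if "NHB" in groups:
        out["NHB"] = np.array([hydrogen_bonds(structure, target)], dtype=float)
    if "IR-NHB" in groups:
        out["IR-NHB"] = np.array([interface_hydrogen_bonds(structure, iface)], dtype=float)
    if {"CFAA", "CFNA"} & set(groups):
        cf = contact_features(structure, target, cutoff=cutoff)
        for g in {"CFAA", "CFNA"} & set(groups):
            out[g] = cf[g]
    if {"IR-CFAA", "IR-CFNA"} & set(groups):
        ircf = interface_contact_features(structure, iface, cutoff=cutoff)
        for g in {"IR-CFAA", "IR-CFNA"} & set(groups):
            out[g] = ircf[g]

    profile_map = None
    target_row = None
    if profile is not None:
        mapping = profile.map_to_chain(structure, target.chain)
        profile_map = {k: (profile, i) for k, i in mapping.items()}
        target_row = profile_map.get(target)
    if "JSD" in groups:
        if target_row is None:
            raise FeatureError(
                "JSD group requires a conservation profile covering the mutated chain"
            )
        out["JSD"] = np.array([jsd_conservation(*target_row)])
    if "ENDES" in groups:
        out["ENDES"] = endes_scores(provider, structure, target, iface, target_row)
    if "IR-ENDES" in groups:
        out["IR-ENDES"] = interface_endes_scores(provider, structure, iface, profile_map)
    return {g: out[g] for g in groups}


def assemble_nonenergy_block(
    structure_wt: ComplexStructure,
    structure_mut: ComplexStructure,
    mutation: MutationRecord,
    iface: InterfaceSet,
    profile: Optional[ConservationProfile] = None,
    provider=None,
    groups=None,
    **kwargs,
) -> dict[str, NonEnergyFeatureBlock]:
    """Nonenergy feature blocks: wild-type values and mut-wt differences.

    The mutant state reuses the wild-type interface membership; the profile
    (sequence-derived) is shared between states.
    """
    if mutation.monomer_key is None:
        raise ValueError("mutation must be bound to the structure first")
    target = mutation.monomer_key
    wt = state_nonenergy_values(
        structure_wt, target, iface, profile=profile, provider=provider,
        groups=groups, **kwargs,
    )
    mut = state_nonenergy_values(
        structure_mut, target, iface, profile=profile, provider=provider,
        groups=groups, **kwargs,
    )
    return {
        g: NonEnergyFeatureBlock(group=g, wt=wt[g], diff=mut[g] - wt[g]) for g in wt
    }
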