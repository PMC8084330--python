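"""Comparative statistics between mutation classes.

Group-wise summaries of experimental ddG (by wild-type residue type, Levy
location class or major binding mode), the root-mean-square distance
between two 20-residue-type mean profiles, dissection of a mutated
residue's major binding mode from its atomic contacts with nucleotides,
and rank-based significance testing between two ddG samples.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu

from ._chemdata import AA_ORDER
from .modeling import Dataset
from .structure_io import ComplexStructure, InterfaceSet, MonomerKey

log = logging.getLogger(__name__)


def group_summary(
    ds: Dataset, grouping: Union[str, Mapping, Callable]
) -> pd.DataFrame:
    """Per-group count, mean and standard deviation of experimental ddG.

    ``grouping`` is ``"wt_residue"``, a mapping from mutation label to a
    group key, or a callable of the mutation record.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    if grouping == "wt_residue":
        keys = [r.wt_code for r in ds.records]
    elif callable(grouping):
        keys = [grouping(r) for r in ds.records]
    else:
        try:
            keys = [grouping[r.label] for r in ds.records]
        except KeyError as exc:
            raise ValueError(f"grouping unresolvable for mutation {exc}") from None
    df = pd.DataFrame({"group": keys, "ddg": ds.ddg})
    out = df.groupby("group")["ddg"].agg(n="count", mean="mean", std="std")
    return out.sort_index()


def group_distance(
    means_a: Mapping[str, float],
    means_b: Mapping[str, float],
    impute: float = 0.0,
) -> float:
    """Root-mean-square distance between two residue-type ddG mean profiles.

    ``sqrt((1/20) * sum_i (mean_i - mean'_i)^2)`` over the 20 amino-acid
    types; types missing from a profile are imputed (default 0, logged).
    """
    diffs = []
    for aa in AA_ORDER:
        if aa not in means_a or aa not in means_b:
            log.warning("residue type %s missing from a mean profile; imputing %.3g",
                        aa, impute)
        a = means_a.get(aa, impute)
        b = means_b.get(aa, impute)
        diffs.append(a - b)
    return float(np.sqrt(np.mean(np.square(diffs))))


class BindingMode(NamedTuple):
    nucleotide: str  # one-letter nucleotide code, or "none"
    subunit: str  # phosphate | sugar | nucleobase | none
    contact_class: str  # e.g. sidechain-nucleobase, or "none"


def major_binding_mode(
    structure: ComplexStructure,
    target: MonomerKey,
    cutoff: float = 5.0,
) -> BindingMode:
    """Dominant nucleotide type, nucleotide subunit and contact class of the
    target residue's atomic contacts with nucleotides (< cutoff, heavy atoms).

    The contact class crosses the residue atom class (backbone/sidechain)
    with the nucleotide side (nucleobase vs backbone, where backbone is
    sugar + phosphate). Ties resolve lexicographically; a residue with no
    nucleic contact gets the designated "none" mode.
    """
    t = structure.monomer(target)
    t_heavy = t.heavy_atoms
    t_coords = t.heavy_coords
    nuc_tally: dict[str, int] = {}
    sub_tally: dict[str, int] = {}
    class_tally: dict[str, int] = {}
    for nuc in structure.nucleic_monomers:
        d = cdist(t_coords, nuc.heavy_coords)
        ii, jj = np.nonzero(d < cutoff)
        nuc_heavy = nuc.heavy_atoms
        for i, j in zip(ii, jj):
            res_side = "backbone" if t_heavy[i].record_class == "backbone" else "sidechain"
            sub = nuc_heavy[j].record_class  # phosphate | sugar | nucleobase
            nuc_side = "nucleobase" if sub == "nucleobase" else "backbone"
            nuc_tally[nuc.code] = nuc_tally.get(nuc.code, 0) + 1
            sub_tally[sub] = sub_tally.get(sub, 0) + 1
            key = f"{res_side}-{nuc_side}"
            class_tally[key] = class_tally.get(key, 0) + 1
    if not nuc_tally:
        return BindingMode("none", "none", "none")

    def major(tally: dict[str, int]) -> str:
        return min(tally, key=lambda k: (-tally[k], k))  # ties -> lexicographic

    return BindingMode(major(nuc_tally), major(sub_tally), major(class_tally))


SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p: float) -> str:
    """Half-open star tiers: ***  p<0.001; ** 0.001<=p<0.01; * 0.01<=p<0.05."""
    for bound, stars in SIGNIFICANCE_TIERS:
        if p < bound:
            return stars
    return "ns"


def compare_distributions(values_a, values_b) -> tuple[float, str]:
    """Two-sided Mann-Whitney U test between two ddG samples, with star tier."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least three values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # all values identical: no evidence of difference
        return 1.0, "ns"
    p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if not np.isfinite(p):
        p = 1.0
    return p, significance_tier(p)
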