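"""Virtual-mating estimation of at-risk couples (ARCs).

All possible within-ancestry pairings, sex-blind, are evaluated: a couple is
at risk when both partners carry P/LP variants in the same severe autosomal
recessive gene, unless every cross-partner variant pair falls inside the
exclusion list (variants pathogenic only in trans with a more severe
allele — an offspring homozygous or compound heterozygous for excluded
variants is not considered affected).

The fast counter never materialises all ~15 M pairs: it walks severe genes,
enumerates carrier pairs, subtracts both-only-excluded pairs, and
de-duplicates couples across genes; it is exactly equivalent to the
brute-force all-pairs evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .ingest import CohortBundle

CarrierProfile = dict[str, set[str]]  # gene -> carried P/LP variant keys


@dataclass
class ARCResult:
    ancestry: str
    total_pairs: int
    at_risk: int
    per_gene: dict[str, int] = field(default_factory=dict)

    @property
    def proportion(self) -> float:
        return self.at_risk / self.total_pairs if self.total_pairs else 0.0


def count_pairs(n: int) -> int:
    """Number of distinct couples among n individuals: n(n-1)/2."""
    if n < 0:
        raise ValueError("group size must be non-negative")
    return n * (n - 1) // 2


def couple_at_risk(a: CarrierProfile, b: CarrierProfile,
                   exclusion: set[str]) -> tuple[bool, list[str]]:
    """Risk verdict for one theoretical couple.

    For each shared gene, a cross-partner variant pair (va, vb) is damaging
    unless both members are exclusion-listed (which covers the homozygous
    excluded case va == vb); the couple is at risk for the gene iff some
    damaging pair exists."""
    risk_genes = []
    for gene in a.keys() & b.keys():
        damaging = any(
            not (va in exclusion and vb in exclusion)
            for va in a[gene] for vb in b[gene])
        if damaging:
            risk_genes.append(gene)
    return bool(risk_genes), sorted(risk_genes)


def build_profiles(bundle: CohortBundle, classes: pd.DataFrame,
                   include_xl: bool = False) -> dict[str, CarrierProfile]:
    """Carrier profiles over severe recessive genes (AR by default; the
    X-linked mode is off, matching the autosomal scope of the estimate)."""
    modes = {"AR"} | ({"XL"} if include_xl else set())
    severe = {g for g, row in bundle.catalog.iterrows()
              if bool(row.get("severe", 0))
              and row.get("inheritance") in modes}
    plp_keys = classes.index[classes["category"] == "P/LP"]
    profiles: dict[str, CarrierProfile] = {}
    sample_ids = list(bundle.samples.index)
    for key in plp_keys:
        gene = bundle.variants.loc[key, "gene"]
        if gene not in severe:
            continue
        row = bundle.dosage[bundle.var_index(key)]
        for s in np.flatnonzero(row > 0):
            profiles.setdefault(sample_ids[s], {}) \
                .setdefault(gene, set()).add(key)
    return profiles


def estimate_arc_rate(profiles: dict[str, CarrierProfile],
                      exclusion: set[str], group_samples: list[str],
                      ancestry: str = "all") -> ARCResult:
    """Fast exhaustive-mating count for one ancestry group.

    ``group_samples`` is the full group (carriers and non-carriers); only
    carriers of severe-gene variants can form at-risk couples, so the walk
    is over per-gene carrier lists with couple de-duplication across genes.
    """
    group = set(group_samples)
    by_gene: dict[str, list[str]] = {}
    for sid in group_samples:
        for gene in profiles.get(sid, {}):
            by_gene.setdefault(gene, []).append(sid)
    seen: set[tuple[str, str]] = set()
    per_gene: dict[str, int] = {}
    for gene, carriers in sorted(by_gene.items()):
        only_excluded = [s for s in carriers
                         if profiles[s][gene] <= exclusion]
        n_c, n_e = len(carriers), len(only_excluded)
        per_gene[gene] = count_pairs(n_c) - count_pairs(n_e)
        if per_gene[gene] == 0:
            continue
        excl_set = set(only_excluded)
        for s1, s2 in combinations(sorted(carriers), 2):
            if s1 in excl_set and s2 in excl_set:
                continue
            seen.add((s1, s2))
    return ARCResult(ancestry=ancestry,
                     total_pairs=count_pairs(len(group)),
                     at_risk=len(seen), per_gene=per_gene)


def brute_force_arc(profiles: dict[str, CarrierProfile],
                    exclusion: set[str], group_samples: list[str],
                    ancestry: str = "all") -> ARCResult:
    """Reference all-pairs evaluation (oracle for the fast counter)."""
    at_risk = 0
    per_gene: dict[str, int] = {}
    for s1, s2 in combinations(sorted(group_samples), 2):
        risky, genes = couple_at_risk(profiles.get(s1, {}),
                                      profiles.get(s2, {}), exclusion)
        if risky:
            at_risk += 1
            for g in genes:
                per_gene[g] = per_gene.get(g, 0) + 1
    return ARCResult(ancestry=ancestry,
                     total_pairs=count_pairs(len(group_samples)),
                     at_risk=at_risk, per_gene=per_gene)
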