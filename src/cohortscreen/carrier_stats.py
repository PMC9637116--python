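"""Ancestry-stratified carrier frequencies and cross-group comparisons.

A carrier is an individual with at least one qualifying P/LP allele in a
gene: heterozygotes, homozygotes and compound heterozygotes count once, as
do X-linked hemizygous males; configured in-cis variant pairs are merged to
a single countable event. Adjusted carrier frequency uses the total
individuals of the ancestry group as the denominator.

Group comparisons use the two-sided Fisher exact test (conditional-MLE odds
ratio with exact CI) with Benjamini–Hochberg correction across whatever
family of comparisons is emitted in one analysis table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ingest import CohortBundle
from .utils import pct


def gene_carrier_flags(bundle: CohortBundle, classes: pd.DataFrame,
                       gene: str, category: str = "P/LP") -> np.ndarray:
    """Per-sample boolean: carries >=1 allele of a ``category`` variant in
    ``gene`` (post-QC; no-calls do not contribute)."""
    keys = classes.index[(classes["category"] == category)
                         & (bundle.variants.loc[classes.index, "gene"]
                            == gene)]
    if len(keys) == 0:
        return np.zeros(bundle.n_samples, dtype=bool)
    rows = [bundle.var_index(k) for k in keys]
    return (bundle.dosage[rows] > 0).any(axis=0)


def carrier_matrix(bundle: CohortBundle, classes: pd.DataFrame,
                   category: str = "P/LP") -> pd.DataFrame:
    """samples x genes boolean carrier matrix for one category."""
    genes = sorted(bundle.variants.loc[classes.index, "gene"]
                   [classes["category"] == category].unique())
    data = {g: gene_carrier_flags(bundle, classes, g, category)
            for g in genes}
    return pd.DataFrame(data, index=bundle.samples.index)


def adjusted_carrier_frequency(flags: np.ndarray) -> dict:
    """Carrier-table cell from per-individual carrier flags of one ancestry
    group: count, group size, and adjusted carrier frequency in % (2 d.p.,
    denominator = all individuals of the group)."""
    flags = np.asarray(flags, bool)
    if flags.size == 0:
        raise ValueError("empty ancestry group")
    count = int(flags.sum())
    return {"carriers": count, "n": flags.size,
            "carrier_freq_pct": pct(count, flags.size)}


def carrier_table(bundle: CohortBundle, classes: pd.DataFrame,
                  ancestry: np.ndarray, genes: list[str] | None = None,
                  category: str = "P/LP",
                  sample_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Adjusted per-gene per-ancestry carrier table (Table-1 layout).

    ``ancestry``: per-sample assigned labels; ``sample_mask`` restricts both
    numerator and denominator (e.g. the age <= 50 survivorship check)."""
    mask = np.ones(bundle.n_samples, bool) if sample_mask is None \
        else np.asarray(sample_mask, bool)
    mat = carrier_matrix(bundle, classes, category)
    genes = genes if genes is not None else list(mat.columns)
    rows = []
    for anc in sorted(set(ancestry)):
        in_group = (ancestry == anc) & mask
        size = int(in_group.sum())
        for g in genes:
            flags = mat[g].to_numpy()[in_group] if g in mat else \
                np.zeros(size, bool)
            cell = adjusted_carrier_frequency(flags) if size else \
                {"carriers": 0, "n": 0, "carrier_freq_pct": 0.0}
            rows.append({"gene": g, "ancestry": anc, **cell})
    return pd.DataFrame(rows)


def variant_carrier_table(bundle: CohortBundle, classes: pd.DataFrame,
                          ancestry: np.ndarray,
                          category: str = "P/LP") -> pd.DataFrame:
    """Variant-level carrier counts with in-cis pairs merged to one event."""
    keys = list(classes.index[classes["category"] == category])
    merged: dict[str, list[str]] = {k: [k] for k in keys}
    for k1, k2 in bundle.in_cis:
        if k1 in merged and k2 in merged:
            merged[k1] = [k1, k2]
            del merged[k2]
    rows = []
    for anc in sorted(set(ancestry)):
        in_group = ancestry == anc
        size = int(in_group.sum())
        for event, members in merged.items():
            idx = [bundle.var_index(k) for k in members]
            carried = (bundle.dosage[idx] > 0).any(axis=0)
            count = int(carried[in_group].sum())
            rows.append({
                "event": "+".join(members), "gene":
                    bundle.variants.loc[members[0], "gene"],
                "ancestry": anc, "carriers": count, "n": size,
                "carrier_freq_pct": pct(count, size) if size else 0.0})
    return pd.DataFrame(rows)


def cohort_prevalence(flags: np.ndarray) -> float:
    """Percentage of individuals flagged as carrying >=1 qualifying variant,
    rounded to 2 d.p."""
    flags = np.asarray(flags, bool)
    if flags.size == 0:
        raise ValueError("empty cohort")
    return pct(int(flags.sum()), flags.size)


def panel_prevalence(bundle: CohortBundle, classes: pd.DataFrame,
                     panel: str, category: str = "P/LP") -> dict:
    """Prevalence of >=1 ``category`` variant in genes of a catalog panel."""
    panel_genes = [g for g, row in bundle.catalog.iterrows()
                   if panel in str(row.get("panels", "")).split(",")]
    mat = carrier_matrix(bundle, classes, category)
    cols = [g for g in panel_genes if g in mat.columns]
    flags = mat[cols].to_numpy().any(axis=1) if cols else \
        np.zeros(bundle.n_samples, bool)
    return {"panel": panel, "carriers": int(flags.sum()),
            "n": bundle.n_samples,
            "prevalence_pct": cohort_prevalence(flags), "flags": flags}


@dataclass(frozen=True)
class GroupComparison:
    label: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    p_adjusted: float | None = None


def fisher_group_comparison(k1: int, n1: int, k2: int, n2: int,
                            label: str = "") -> GroupComparison:
    """Two-sided Fisher exact comparison of carrier proportions k1/n1 vs
    k2/n2, with the conditional-MLE odds ratio and exact 95% CI."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("carrier counts must lie within group sizes")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    res = stats.contingency.odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    return GroupComparison(label, ((k1, n1 - k1), (k2, n2 - k2)),
                           float(res.statistic), float(ci.low),
                           float(ci.high), float(p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_across_ancestries(table: pd.DataFrame,
                              group_a: str, group_b: str) -> pd.DataFrame:
    """Per-gene Fisher comparisons between two ancestry groups with BH
    correction over the emitted family (all genes in ``table``)."""
    rows = []
    for gene, sub in table.groupby("gene"):
        a = sub[sub["ancestry"] == group_a].iloc[0]
        b = sub[sub["ancestry"] == group_b].iloc[0]
        cmp_ = fisher_group_comparison(int(a["carriers"]), int(a["n"]),
                                       int(b["carriers"]), int(b["n"]),
                                       label=gene)
        rows.append({"gene": gene, "groups": f"{group_a}_vs_{group_b}",
                     "odds_ratio": cmp_.odds_ratio, "ci_low": cmp_.ci_low,
                     "ci_high": cmp_.ci_high, "p": cmp_.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = bh_adjust(out["p"].to_numpy())
        out["bh_family"] = f"pairwise_{group_a}_{group_b}_n{len(out)}"
    return out
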