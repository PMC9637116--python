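"""Pharmacogene phenotype assignment and disease-risk intersection.

Star-allele / rsID diplotypes are consumed, not called: the input is a
per-sample table of allele pairs with CPIC-style function labels
(increased / normal / decreased / none). A shipped, editable rule table maps
unordered function pairs to metabolizer phenotypes (UM/RM/NM/IM/PM and
gene-specific risk categories) with per-gene actionability flags — CPIC
guidance versions over time, so the table is data, not code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CDC_TIER1_MAP, PGX_LOF_GENES
from .consequences import is_lof
from .utils import pct

FUNCTIONS = ("increased", "normal", "decreased", "none")


class PhenotypeRules:
    """Per-gene mapping from unordered allele-function pairs to phenotype.

    The mapping is total over the four known function labels for every gene
    it declares; unknown functions map to a flagged non-actionable result.
    """

    def __init__(self, table: pd.DataFrame):
        self._map: dict[tuple[str, str, str], tuple[str, bool]] = {}
        self.genes = set(table["gene"])
        for row in table.itertuples(index=False):
            pair = tuple(sorted((row.function1, row.function2)))
            self._map[(row.gene, *pair)] = (row.phenotype, bool(row.actionable))

    def lookup(self, gene: str, f1: str, f2: str) -> tuple[str, bool]:
        if gene not in self.genes:
            raise KeyError(f"gene {gene} absent from phenotype rules")
        if f1 not in FUNCTIONS or f2 not in FUNCTIONS:
            return "Indeterminate", False
        return self._map[(gene, *sorted((f1, f2)))]


def load_phenotype_rules(path: str | Path | None = None) -> PhenotypeRules:
    """Load the shipped (or a user-edited) phenotype rule table."""
    if path is None:
        ref = resources.files("cohortscreen.data") / "pgx_phenotype_rules.tsv"
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    return PhenotypeRules(table)


@dataclass(frozen=True)
class Diplotype:
    sample_id: str
    gene: str
    allele1: str
    allele2: str
    function1: str
    function2: str


def assign_pgx_phenotype(dip: Diplotype, rules: PhenotypeRules) -> tuple[str, bool]:
    """Phenotype and actionability for one diplotype (order-symmetric)."""
    return rules.lookup(dip.gene, dip.function1, dip.function2)


def assign_all_phenotypes(diplotypes: pd.DataFrame,
                          rules: PhenotypeRules) -> pd.DataFrame:
    """Vectorised phenotype assignment over a diplotype table.

    Returns the table with ``phenotype`` and ``actionable`` columns added.
    """
    out = diplotypes.copy()
    phenos, actions = [], []
    for row in out.itertuples(index=False):
        ph, act = rules.lookup(row.gene, row.function1, row.function2)
        phenos.append(ph)
        actions.append(act)
    out["phenotype"] = pd.Series(phenos, index=out.index, dtype=object)
    out["actionable"] = pd.Series(actions, index=out.index, dtype=bool)
    return out


def actionable_summary(phenotypes: pd.DataFrame,
                       ancestry: pd.Series) -> dict:
    """Cohort-level actionable-phenotype tabulation.

    ``phenotypes``: output of :func:`assign_all_phenotypes`;
    ``ancestry``: sample_id -> ancestry label for every cohort individual
    (the denominator of cohort fractions).

    Returns per-gene per-ancestry actionable fractions, the fraction of
    individuals with >=1 actionable finding, and the median number of
    findings per individual.
    """
    n_total = len(ancestry)
    act = phenotypes[phenotypes["actionable"]]
    counts = act.groupby("sample_id").size()
    per_ind = counts.reindex(ancestry.index, fill_value=0)
    per_gene = {}
    anc_sizes = ancestry.value_counts().to_dict()
    for gene, sub in phenotypes.groupby("gene"):
        sub = sub.set_index("sample_id")
        per_gene[gene] = {}
        for anc, size in sorted(anc_sizes.items()):
            ids = ancestry.index[ancestry == anc]
            flag = sub.loc[sub.index.intersection(ids), "actionable"]
            per_gene[gene][anc] = {
                "carriers": int(flag.sum()), "n": int(size),
                "pct": pct(int(flag.sum()), size, 1)}
    n_any = int((per_ind > 0).sum())
    return {
        "per_gene": per_gene,
        "n_with_actionable": n_any,
        "n_total": n_total,
        "pct_with_actionable": pct(n_any, n_total, 1),
        "median_findings": float(np.median(per_ind.to_numpy())),
    }


def pharmacogene_lof_screen(annotations: pd.DataFrame,
                            known_allele_keys: set[str],
                            manual_removals: set[str] = frozenset(),
                            genes: tuple[str, ...] = PGX_LOF_GENES,
                            max_af: float = 0.01) -> pd.DataFrame:
    """Screen designated pharmacogenes for putative novel LOF variants.

    Emits LOF-consequence variants on MANE transcripts of the configured
    genes that are not catalogued pharmacogenetic alleles, have MAF below
    ``max_af``, and carry a PVS1 "Very Strong" label. Variants on a manual
    removal list (e.g. failed coverage review) are excluded.
    """
    ann = annotations
    keys = (ann["chrom"].astype(str) + ":" + ann["pos"].astype(str)
            + ":" + ann["ref"] + ":" + ann["alt"])
    mask = (
        ann["gene"].isin(genes)
        & ann["consequence"].map(is_lof)
        & (ann["is_mane"] == 1)
        & ~keys.isin(known_allele_keys)
        & (pd.to_numeric(ann["af"], errors="coerce").fillna(0.0) < max_af)
        & (ann["pvs1"].fillna("") == "Very Strong")
        & ~keys.isin(manual_removals)
    )
    out = ann.loc[mask].copy()
    out["key"] = keys[mask]
    return out


def cdc_tier1_intersection(condition_carriers: dict[str, set[str]],
                           phenotypes: pd.DataFrame,
                           tier1_map: dict | None = None) -> dict:
    """Intersect CDC Tier 1 at-risk carriers with actionable PGx phenotypes.

    ``condition_carriers``: condition -> sample ids carrying a P/LP variant
    in the condition's genes. ``phenotypes``: assigned diplotype phenotypes.
    For each condition only the mapped drug-relevant pharmacogene counts
    (e.g. tamoxifen/CYP2D6 for HBOC).
    """
    tier1_map = tier1_map or CDC_TIER1_MAP
    result: dict = {"per_condition": {}}
    at_risk_all: set[str] = set()
    joint_all: set[str] = set()
    for cond, m in tier1_map.items():
        carriers = set(condition_carriers.get(cond, set()))
        sub = phenotypes[(phenotypes["gene"] == m["pgx_gene"])
                         & phenotypes["phenotype"].isin(m["pgx_phenotypes"])]
        flagged = set(sub["sample_id"])
        joint = carriers & flagged
        at_risk_all |= carriers
        joint_all |= joint
        result["per_condition"][cond] = {
            "at_risk": len(carriers),
            "joint": len(joint),
            "pct": pct(len(joint), len(carriers), 1) if carriers else 0.0,
            "joint_ids": sorted(joint),
        }
    result["overall"] = {
        "at_risk": len(at_risk_all),
        "joint": len(joint_all),
        "pct": pct(len(joint_all), len(at_risk_all), 1) if at_risk_all else 0.0,
    }
    return result
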