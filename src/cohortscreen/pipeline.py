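"""End-to-end orchestration: bundle -> classification -> all analyses.

Thin glue used by the numbered analysis scripts, the test suite and the
acceptance script; each step lives in its own module.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import ancestry as anc_mod
from . import arc as arc_mod
from . import carrier_stats as cs
from . import pgx as pgx_mod
from .classifier import ClassifierConfig, classify_all, filter_all_deletions
from .config import ANCESTRIES
from .gene_catalog import panel_gap_analysis
from .ingest import CohortBundle, load_bundle


class PipelineResult:
    """Bag of per-stage outputs (attribute access only)."""

    def __init__(self, **kw):
        self.__dict__.update(kw)


def run_pipeline(bundle: CohortBundle | str | Path,
                 config: ClassifierConfig = ClassifierConfig(),
                 qc: bool = True) -> PipelineResult:
    if not isinstance(bundle, CohortBundle):
        bundle = load_bundle(bundle, qc=qc)
    classes = classify_all(bundle.variants, bundle.dosage, bundle.catalog,
                           bundle.evidence, config)
    assigned, maxq = anc_mod.assign_all(bundle.Q)
    assigned_s = pd.Series(assigned, index=bundle.samples.index)
    re_mismatch = pd.Series(
        [anc_mod.flag_re_mismatch(sr, a) for sr, a in
         zip(bundle.samples["self_reported"], assigned)],
        index=bundle.samples.index)

    gene_table = cs.carrier_table(bundle, classes, assigned)
    prev = {p: cs.panel_prevalence(bundle, classes, p)
            for p in ("acmg_sf_v2", "acmg_sf_v3")}

    profiles = arc_mod.build_profiles(bundle, classes)
    arc_results = {}
    for anc in ANCESTRIES:
        group = list(bundle.samples.index[assigned == anc])
        if len(group) >= 2:
            arc_results[anc] = arc_mod.estimate_arc_rate(
                profiles, bundle.exclusion, group, ancestry=anc)

    seg_index = anc_mod.SegmentIndex(bundle.segments)
    specific = anc_mod.ancestry_specific_variants(bundle, classes, seg_index)
    discordant = anc_mod.discordant_carriers(specific, assigned_s,
                                             ~re_mismatch.astype(bool))
    disc_flag = bundle.samples.index.isin(discordant["sample_id"])
    enrichment = anc_mod.admixture_enrichment(disc_flag, maxq, assigned) \
        if disc_flag.any() else {"comparison": None, "per_ancestry": {}}

    # per-gene max carrier frequency across ancestries (fractions)
    max_freq = (gene_table.assign(f=gene_table["carriers"]
                                  / gene_table["n"].clip(lower=1))
                .groupby("gene")["f"].max())
    gaps = panel_gap_analysis(max_freq, bundle.catalog)

    rules = pgx_mod.load_phenotype_rules()
    phenos = pgx_mod.assign_all_phenotypes(bundle.pgx, rules)
    pgx_summary = pgx_mod.actionable_summary(phenos, assigned_s)
    carrier_mat = cs.carrier_matrix(bundle, classes)
    condition_carriers = {}
    for cond, m in pgx_mod.CDC_TIER1_MAP.items():
        cols = [g for g in m["genes"] if g in carrier_mat.columns]
        flags = carrier_mat[cols].any(axis=1) if cols else \
            pd.Series(False, index=carrier_mat.index)
        condition_carriers[cond] = set(flags.index[flags])
    tier1 = pgx_mod.cdc_tier1_intersection(condition_carriers, phenos)
    lof_screen = pgx_mod.pharmacogene_lof_screen(
        bundle.variants.reset_index(), bundle.pgx_known,
        bundle.pgx_removals)
    sv_table = filter_all_deletions(bundle.svs, bundle.catalog) \
        if len(bundle.svs) else pd.DataFrame(
            columns=["id", "pass", "gene", "reasons"])

    return PipelineResult(
        bundle=bundle, classes=classes, assigned=assigned, maxq=maxq,
        re_mismatch=re_mismatch, gene_table=gene_table, prevalence=prev,
        profiles=profiles, arc=arc_results, specific=specific,
        discordant=discordant, enrichment=enrichment, gaps=gaps,
        phenotypes=phenos, pgx_summary=pgx_summary, tier1=tier1,
        condition_carriers=condition_carriers, lof_screen=lof_screen,
        svs=sv_table)
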