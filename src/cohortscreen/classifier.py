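"""Rule-based variant classification.

Every retained variant receives exactly one category:

* **P/LP** — Tier1A_TwoPlus (ClinVar >=2-gold-star P/LP, or a novel SNV
  reproducing a known TwoPlus amino-acid change), Tier1A_Conflicting
  (conflicting interpretations with >=4 P/LP submissions), or Tier1B (LOF
  consequence on the MANE/clinically relevant transcript backed by a PVS1
  "Very Strong" label or >=2 TwoPlus P/LP variants downstream on the
  transcript).
* **VUS-FP** — a VUS favouring pathogenicity: missense with REVEL > 0.7
  inside a ClinVar P/LP hotspot, or a cryptic splice variant with SpliceAI
  max > 0.8 in a gene with >=5 TwoPlus P/LP LOF variants.
* **VUS** — everything interpretable that meets no P/LP criterion, including
  conflicting records with 1–3 P/LP submissions (flagged for manual review)
  and close-proximity frameshift pairs whose net length change restores the
  reading frame.
* **Unclassified** — benign-aggregate ClinVar records and variants offering
  nothing to interpret.

A hotspot is a 25-bp rolling window holding more than two TwoPlus P/LP
variants and fewer benign/likely-benign than P/LP variants; windows are
computed on genomic coordinates at 1-bp steps from variant start positions.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consequences import is_lof
from .gene_catalog import lofi_genes


@dataclass(frozen=True)
class ClassifierConfig:
    revel_min: float = 0.7            # strict >
    spliceai_min: float = 0.8         # strict >
    hotspot_window_bp: int = 25
    hotspot_min_plp: int = 3          # ">2" TwoPlus P/LP in window
    gene_lof_min_for_splice: int = 5
    conflicting_plp_auto: int = 4
    downstream_plp_min: int = 2
    retention_af: float = 0.05
    fs_pair_window_bp: int = 30
    benign_requires_twoplus: bool = True


@dataclass(frozen=True)
class ClassificationResult:
    category: str                     # P/LP | VUS-FP | VUS | Unclassified
    tier: str = "none"                # Tier1A_TwoPlus | Tier1A_Conflicting |
                                      # Tier1B | none
    rationale: tuple[str, ...] = ()
    needs_manual_review: bool = False

    def __post_init__(self):
        if (self.tier != "none") != (self.category == "P/LP"):
            raise ValueError("tier set iff category is P/LP")


PLP = "P/LP"
VUSFP = "VUS-FP"
VUS = "VUS"
UNCLASSIFIED = "Unclassified"


# --------------------------------------------------------------------------
# evidence index


class EvidenceIndex:
    """Lookup structures over a ClinVar-style evidence table."""

    def __init__(self, evidence: pd.DataFrame,
                 config: ClassifierConfig = ClassifierConfig()):
        self.config = config
        ev = evidence
        stars = ev["review_stars"].fillna(0).astype(int)
        cls = ev["classification"].fillna("")
        self.records = {row.key: row for row in ev.itertuples(index=False)}
        twoplus_plp = ev[(stars >= 2) & (cls == "P/LP")]
        self.twoplus_plp_keys = set(twoplus_plp["key"])
        self.plp_positions: dict[str, list[int]] = {
            g: sorted(sub["pos"]) for g, sub in twoplus_plp.groupby("gene")}
        self.plp_hgvsp = {
            (r.gene, r.hgvsp) for r in twoplus_plp.itertuples(index=False)
            if isinstance(r.hgvsp, str) and r.hgvsp}
        benign = ev[cls == "B/LB"]
        if config.benign_requires_twoplus:
            benign = benign[stars.loc[benign.index] >= 2]
        self.blb_positions: dict[str, list[int]] = {
            g: sorted(sub["pos"]) for g, sub in benign.groupby("gene")}
        self._hotspot_cache: dict[str, list[tuple[int, int]]] = {}

    def hotspots(self, gene: str) -> list[tuple[int, int]]:
        if gene not in self._hotspot_cache:
            self._hotspot_cache[gene] = detect_hotspots(
                self.plp_positions.get(gene, []),
                self.blb_positions.get(gene, []), self.config)
        return self._hotspot_cache[gene]

    def in_hotspot(self, gene: str, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.hotspots(gene))

    def downstream_plp_count(self, gene: str, pos: int, strand: str) -> int:
        """TwoPlus P/LP variants strictly downstream in transcript
        orientation (greater genomic position on '+', smaller on '-')."""
        positions = self.plp_positions.get(gene, [])
        if strand == "-":
            return bisect_left(positions, pos)
        return len(positions) - bisect_right(positions, pos)


def detect_hotspots(plp_positions: list[int], blb_positions: list[int],
                    config: ClassifierConfig = ClassifierConfig()
                    ) -> list[tuple[int, int]]:
    """All qualifying hotspot windows ``[s, s + window - 1]``.

    A window qualifies iff it holds >= ``hotspot_min_plp`` TwoPlus P/LP
    start positions and strictly fewer B/LB than P/LP positions. Candidate
    starts are restricted to windows containing at least one P/LP variant,
    which is exhaustive: any qualifying window holds >= 3 of them.
    """
    w = config.hotspot_window_bp
    plp = sorted(plp_positions)
    blb = sorted(blb_positions)
    windows = []
    starts = sorted({s for p in plp for s in range(p - w + 1, p + 1)})
    for s in starts:
        e = s + w - 1
        n_plp = bisect_right(plp, e) - bisect_left(plp, s)
        if n_plp < config.hotspot_min_plp:
            continue
        n_blb = bisect_right(blb, e) - bisect_left(blb, s)
        if n_blb < n_plp:
            windows.append((s, e))
    return windows


# --------------------------------------------------------------------------
# per-variant rules


def classify_clinvar_evidence(variant: pd.Series, index: EvidenceIndex,
                              config: ClassifierConfig = ClassifierConfig()
                              ) -> ClassificationResult | None:
    """Tier1A evidence rules; returns None when ClinVar evidence decides
    nothing (the variant falls through to the LOF / VUS rules)."""
    key = variant.name if isinstance(variant.name, str) else variant["key"]
    rec = index.records.get(key)
    if key in index.twoplus_plp_keys:
        return ClassificationResult(PLP, "Tier1A_TwoPlus", ("clinvar_twoplus",))
    snv = len(variant["ref"]) == 1 and len(variant["alt"]) == 1
    hgvsp = variant.get("hgvsp", "")
    if snv and isinstance(hgvsp, str) and hgvsp \
            and (variant["gene"], hgvsp) in index.plp_hgvsp \
            and (rec is None or rec.classification != "B/LB"):
        return ClassificationResult(PLP, "Tier1A_TwoPlus",
                                    ("novel_known_codon_change",))
    if rec is None:
        return None
    if rec.conflicting:
        n_plp = int(rec.n_p) + int(rec.n_lp)
        if n_plp >= config.conflicting_plp_auto:
            return ClassificationResult(PLP, "Tier1A_Conflicting",
                                        ("conflicting_ge4_plp",))
        if n_plp >= 1:
            return ClassificationResult(
                VUS, rationale=("conflicting_1to3_plp",),
                needs_manual_review=True)
        if int(rec.n_vus) >= 4:
            return ClassificationResult(VUS, rationale=("conflicting_ge4_vus",))
        return ClassificationResult(VUS, rationale=("conflicting_other",))
    if rec.classification == "B/LB":
        return ClassificationResult(UNCLASSIFIED, rationale=("clinvar_benign",))
    if rec.classification == "VUS":
        return ClassificationResult(VUS, rationale=("clinvar_vus",))
    return None


def classify_tier1b_lof(variant: pd.Series, catalog: pd.DataFrame,
                        index: EvidenceIndex,
                        config: ClassifierConfig = ClassifierConfig()
                        ) -> ClassificationResult:
    """PVS1-style LOF rule for variants not resolved by Tier1A."""
    gene = variant["gene"]
    if gene not in catalog.index:
        return ClassificationResult(UNCLASSIFIED,
                                    rationale=("gene_absent_from_catalog",))
    row = catalog.loc[gene]
    if gene == "TTN":
        # truncating TTN needs dedicated cardio assessment; never automatic
        return ClassificationResult(VUS, rationale=("ttn_truncating",),
                                    needs_manual_review=True)
    mane = row.get("mane_transcript", "")
    clinical = row.get("clinical_tx", "") or ""
    tx = variant.get("transcript", "")
    on_relevant = (bool(variant.get("is_mane", 0)) and tx == mane) \
        or (not mane and tx == clinical and bool(clinical))
    if not on_relevant:
        return ClassificationResult(VUS, rationale=("lof_not_on_mane",))
    if str(variant.get("pvs1", "") or "") == "Very Strong":
        return ClassificationResult(PLP, "Tier1B", ("pvs1_very_strong",))
    strand = str(row.get("strand", "+"))
    if index.downstream_plp_count(gene, int(variant["pos"]),
                                  strand) >= config.downstream_plp_min:
        return ClassificationResult(PLP, "Tier1B", ("twoplus_plp_downstream",))
    return ClassificationResult(VUS, rationale=("lof_unsupported",))


def classify_vus_fp(variant: pd.Series, catalog: pd.DataFrame,
                    index: EvidenceIndex,
                    config: ClassifierConfig = ClassifierConfig()
                    ) -> ClassificationResult | None:
    """Promote a VUS to VUS-FP on in-silico evidence; None = stays VUS."""
    gene = variant["gene"]
    cons = variant["consequence"]
    revel = pd.to_numeric(pd.Series([variant.get("revel")]),
                          errors="coerce").iloc[0]
    spliceai = pd.to_numeric(pd.Series([variant.get("spliceai_max")]),
                             errors="coerce").iloc[0]
    if cons == "missense_variant" and not pd.isna(revel):
        if revel > config.revel_min and index.in_hotspot(gene,
                                                         int(variant["pos"])):
            return ClassificationResult(VUSFP,
                                        rationale=("missense_revel_hotspot",))
    if not is_lof(cons) and not pd.isna(spliceai):
        if spliceai > config.spliceai_min and gene in catalog.index \
                and int(catalog.loc[gene, "twoplus_plp_lof_count"]) \
                >= config.gene_lof_min_for_splice:
            return ClassificationResult(VUSFP,
                                        rationale=("cryptic_splice_lof_gene",))
    return None


def classify_variant(variant: pd.Series, catalog: pd.DataFrame,
                     index: EvidenceIndex,
                     config: ClassifierConfig = ClassifierConfig()
                     ) -> ClassificationResult:
    """Full rule cascade for one retained variant (Tier1A -> Tier1B ->
    VUS-FP -> VUS -> Unclassified). Frameshift-pair demotion is cohort-level
    and applied by :func:`classify_all`."""
    res = classify_clinvar_evidence(variant, index, config)
    if res is None and is_lof(variant["consequence"]):
        res = classify_tier1b_lof(variant, catalog, index, config)
    if res is None:
        res = _base_uncertain(variant)
    if res.category == VUS and not res.needs_manual_review:
        promoted = classify_vus_fp(variant, catalog, index, config)
        if promoted is not None:
            res = promoted
    return res


def _base_uncertain(variant: pd.Series) -> ClassificationResult:
    """No evidence record, not LOF: VUS when there is something to assess
    (protein-altering/splice consequence or an in-silico score), else
    Unclassified."""
    cons = variant["consequence"]
    revel = pd.to_numeric(pd.Series([variant.get("revel")]),
                          errors="coerce").iloc[0]
    spliceai = pd.to_numeric(pd.Series([variant.get("spliceai_max")]),
                             errors="coerce").iloc[0]
    interpretable = cons in (
        "missense_variant", "inframe_insertion", "inframe_deletion",
        "protein_altering_variant", "splice_region_variant",
        "start_lost", "stop_lost") or not pd.isna(spliceai) \
        or (cons == "intron_variant" and not pd.isna(revel))
    if interpretable:
        return ClassificationResult(VUS, rationale=("no_criteria_met",))
    return ClassificationResult(UNCLASSIFIED, rationale=("fallthrough",))


# --------------------------------------------------------------------------
# cohort-level classification


def _frameshift_pairs(retained: pd.DataFrame, dosage: np.ndarray,
                      full_index: pd.Index,
                      config: ClassifierConfig) -> set[str]:
    """Keys of frameshift variants that pair with a nearby frameshift in the
    same gene, co-occur in at least one sample, and whose net length change
    is a multiple of 3 (net in-frame event -> manual review).

    ``full_index`` maps keys to rows of the dosage matrix (which covers all
    variants, retained or not)."""
    flagged: set[str] = set()
    fs = retained[retained["consequence"] == "frameshift_variant"]
    for gene, sub in fs.groupby("gene"):
        sub = sub.sort_values("pos")
        rows = list(sub.itertuples())
        for a, b in itertools.combinations(rows, 2):
            if abs(b.pos - a.pos) > config.fs_pair_window_bp:
                continue
            net = (len(a.alt) - len(a.ref)) + (len(b.alt) - len(b.ref))
            if net % 3 != 0:
                continue
            ia = full_index.get_loc(a.Index)
            ib = full_index.get_loc(b.Index)
            shared = ((dosage[ia] > 0) & (dosage[ib] > 0)).any()
            if shared:
                flagged.update((a.Index, b.Index))
    return flagged


def classify_all(variants: pd.DataFrame, dosage: np.ndarray,
                 catalog: pd.DataFrame, evidence: pd.DataFrame,
                 config: ClassifierConfig = ClassifierConfig(),
                 overrides: pd.DataFrame | None = None) -> pd.DataFrame:
    """Classify every retained variant; returns a table indexed by variant
    key with category / tier / rationale / needs_manual_review.

    ``overrides``: optional table (key, category, tier) of final manual
    calls, applied last — the automated pipeline is total, but conflicting
    1–3-P/LP records and TTN truncations genuinely need expert curation.
    """
    index = EvidenceIndex(evidence, config)
    retained = variants[variants.get("retained", True) == True]  # noqa: E712
    results = {}
    for key, row in retained.iterrows():
        results[key] = classify_variant(row, catalog, index, config)
    fs_flag = _frameshift_pairs(retained, dosage, variants.index, config)
    for key in fs_flag:
        if results[key].tier != "Tier1A_TwoPlus":
            results[key] = ClassificationResult(
                VUS, rationale=results[key].rationale + ("fs_pair_inframe",),
                needs_manual_review=True)
    out = pd.DataFrame({
        "category": {k: r.category for k, r in results.items()},
        "tier": {k: r.tier for k, r in results.items()},
        "rationale": {k: ";".join(r.rationale) for k, r in results.items()},
        "needs_manual_review": {k: r.needs_manual_review
                                for k, r in results.items()},
    })
    out.index.name = "key"
    if overrides is not None:
        for row in overrides.itertuples(index=False):
            if row.key in out.index:
                out.loc[row.key, ["category", "tier"]] = \
                    [row.category, row.tier]
                out.loc[row.key, "needs_manual_review"] = False
    return out.loc[retained.index]


# --------------------------------------------------------------------------
# gross deletions


@dataclass(frozen=True)
class SVDeletion:
    chrom: str
    start: int
    end: int
    dhfc: float
    dhffc: float
    dhbfc: float
    dhsp: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def filter_gross_deletion(sv: SVDeletion | pd.Series, catalog: pd.DataFrame,
                          lofi: set[str] | None = None
                          ) -> tuple[bool, str | None, tuple[str, ...]]:
    """Deletion confirmation filter: 500 bp–10 Mb, duphold depth fold-changes
    (DHFC/DHFFC/DHBFC) all < 0.7, split-read support DHSP > 1, and overlap
    with >=1 MANE-transcript exon of a LOFi gene.

    Returns (pass, affected gene, failure reasons)."""
    if isinstance(sv, pd.Series):
        if any(pd.isna(sv.get(k)) for k in ("dhfc", "dhffc", "dhbfc", "dhsp")):
            return False, None, ("missing_metric",)
        sv = SVDeletion(str(sv["chrom"]), int(sv["start"]), int(sv["end"]),
                        float(sv["dhfc"]), float(sv["dhffc"]),
                        float(sv["dhbfc"]), int(sv["dhsp"]))
    reasons = []
    if not (500 <= sv.length <= 10_000_000):
        reasons.append("length")
    if not (sv.dhfc < 0.7 and sv.dhffc < 0.7 and sv.dhbfc < 0.7):
        reasons.append("depth_fold_change")
    if not sv.dhsp > 1:
        reasons.append("split_read_support")
    lofi = lofi if lofi is not None else lofi_genes(catalog)
    gene_hit = None
    for g, row in catalog.iterrows():
        if g not in lofi or str(row["chrom"]) != sv.chrom:
            continue
        if sv.start <= int(row["mane_exon_end"]) \
                and sv.end >= int(row["mane_exon_start"]):
            gene_hit = g
            break
    if gene_hit is None:
        reasons.append("no_lofi_mane_exon_overlap")
    return (not reasons), gene_hit, tuple(reasons)


def filter_all_deletions(svs: pd.DataFrame, catalog: pd.DataFrame
                         ) -> pd.DataFrame:
    lofi = lofi_genes(catalog)
    rows = []
    for _, sv in svs.iterrows():
        ok, gene, reasons = filter_gross_deletion(sv, catalog, lofi)
        rows.append({"id": sv["id"], "pass": ok, "gene": gene,
                     "reasons": ";".join(reasons)})
    return pd.DataFrame(rows)
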