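"""Bundle ingestion: VCF + tables into the internal cohort model.

Applies the heterozygote re-qualification rule (allele balance 20–80 %,
DP >= 5, GQ >= 20; failing het calls become no-calls), selects one
transcript consequence per variant (MANE first, then most deleterious, then
longest transcript), and applies the curation retention filter (ClinVar
record or cohort allele frequency < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .consequences import severity_rank
from .utils import variant_key

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    ab_low: float = 0.20
    ab_high: float = 0.80
    min_dp: int = 5
    min_gq: int = 20

    def __post_init__(self):
        if not (0.0 <= self.ab_low < self.ab_high <= 1.0):
            raise ValueError("require 0 <= ab_low < ab_high <= 1")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    gt: tuple[int, int] | None  # allele indices; None = no-call
    ad: tuple[int, int] = (0, 0)
    dp: int = 0
    gq: int = 0

    @property
    def is_het(self) -> bool:
        return self.gt is not None and self.gt[0] != self.gt[1]


def requalify_heterozygote(call: GenotypeCall,
                           thresholds: QCThresholds = QCThresholds()
                           ) -> GenotypeCall:
    """Re-genotype a heterozygous call to no-call unless allele balance,
    depth and genotype quality all pass. Homozygous and no-call inputs are
    returned unchanged; a het with zero total allele depth has undefined
    balance and becomes a no-call."""
    if not call.is_het:
        return call
    total = call.ad[0] + call.ad[1]
    if total == 0:
        return replace(call, gt=None)
    ab = call.ad[1] / total
    ok = (thresholds.ab_low <= ab <= thresholds.ab_high
          and call.dp >= thresholds.min_dp and call.gq >= thresholds.min_gq)
    return call if ok else replace(call, gt=None)


def requalify_matrix(dosage: np.ndarray, ad_ref: np.ndarray,
                     ad_alt: np.ndarray, dp: np.ndarray, gq: np.ndarray,
                     thresholds: QCThresholds = QCThresholds()
                     ) -> np.ndarray:
    """Vectorised re-qualification over a (variants x samples) dosage matrix;
    failing het calls become -1 (no-call)."""
    total = ad_ref + ad_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(total > 0, ad_alt / np.maximum(total, 1), np.nan)
    het = dosage == 1
    ok = ((ab >= thresholds.ab_low) & (ab <= thresholds.ab_high)
          & (dp >= thresholds.min_dp) & (gq >= thresholds.min_gq))
    out = dosage.copy()
    out[het & ~np.nan_to_num(ok, nan=False).astype(bool)] = -1
    return out


def select_transcript_consequence(annotations: pd.DataFrame,
                                  ) -> pd.Series:
    """Pick one annotation row per variant: the MANE transcript if present,
    else most severe consequence, ties broken by longest transcript then
    lexicographic transcript id. Deterministic under row permutation."""
    if len(annotations) == 0:
        raise ValueError("no annotations for variant")
    ann = annotations.copy()
    if "transcript_length" not in ann.columns:
        ann["transcript_length"] = 0
    ann["_rank"] = ann["consequence"].map(severity_rank)
    mane = ann[ann["is_mane"] == 1]
    pool = mane if len(mane) else ann
    pool = pool.sort_values(
        ["_rank", "transcript_length", "transcript"],
        ascending=[True, False, True], kind="stable")
    return pool.iloc[0].drop(labels=["_rank"])


def retention_filter(af: float | None, in_clinvar: bool) -> bool:
    """Retain a variant for curation iff it has any ClinVar record or a
    cohort allele frequency strictly below 0.05."""
    if in_clinvar:
        return True
    if af is None or (isinstance(af, float) and np.isnan(af)):
        log.warning("variant lacking AF and ClinVar record: dropped")
        return False
    return af < 0.05


def check_unrelated(kinship: pd.DataFrame, threshold: float = 0.0884) -> None:
    """Optionally reject a cohort shipped with a kinship table containing a
    related pair (KING coefficient >= threshold); the pipeline assumes
    pre-pruned unrelated individuals."""
    bad = kinship[kinship["kinship"] >= threshold]
    if len(bad):
        pair = bad.iloc[0]
        raise ValueError(
            f"cohort contains related pair {pair['sample1']}/"
            f"{pair['sample2']} (kinship {pair['kinship']:.4f})")


# --------------------------------------------------------------------------
# bundle loading


@dataclass
class CohortBundle:
    """Everything a pipeline run needs, in memory."""

    samples: pd.DataFrame          # index sample_id: self_reported, sex, age
    Q: np.ndarray                  # (n_samples, 3), columns CH, IND, MY
    variants: pd.DataFrame         # one selected annotation per variant key
    dosage: np.ndarray             # (n_variants, n_samples); -1 = no-call
    hap: np.ndarray                # (n_variants, n_samples, 2) phased alleles
    evidence: pd.DataFrame
    catalog: pd.DataFrame          # gene catalog, index gene
    segments: pd.DataFrame
    svs: pd.DataFrame
    pgx: pd.DataFrame
    exclusion: set = field(default_factory=set)
    in_cis: list = field(default_factory=list)
    pgx_known: set = field(default_factory=set)
    pgx_removals: set = field(default_factory=set)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def var_index(self, key: str) -> int:
        return self.variants.index.get_loc(key)


def _read_vcf(path: Path, sample_ids: list[str], qc: bool,
              thresholds: QCThresholds):
    vcf = VCF(str(path), gts012=False)
    if list(vcf.samples) != sample_ids:
        raise ValueError("VCF sample order disagrees with samples table")
    n = len(sample_ids)
    keys, rows = [], []
    dosage_rows, hap_rows = [], []
    for v in vcf:
        alt = v.ALT[0]
        keys.append(variant_key(v.CHROM, v.POS, v.REF, alt))
        rows.append((v.CHROM, v.POS, v.REF, alt))
        g = np.array(v.genotypes, dtype=np.int16)  # (n, 3): a0, a1, phased
        a0, a1 = g[:, 0], g[:, 1]
        nocall = (a0 < 0) | (a1 < 0)
        dos = np.where(nocall, -1, a0 + a1).astype(np.int8)
        ad = v.format("AD")
        dp = v.format("DP")[:, 0]
        gq = v.format("GQ")[:, 0]
        if qc:
            dos = requalify_matrix(dos[None, :], ad[None, :, 0],
                                   ad[None, :, 1], dp[None, :], gq[None, :],
                                   thresholds)[0]
        hap = np.zeros((n, 2), dtype=np.int8)
        called = dos >= 0
        hap[called, 0] = (a0[called] > 0)
        hap[called, 1] = (a1[called] > 0)
        dosage_rows.append(dos)
        hap_rows.append(hap)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    sites.index = pd.Index(keys, name="key")
    return sites, np.array(dosage_rows, dtype=np.int8), \
        np.array(hap_rows, dtype=np.int8)


def _read_svs(path: Path) -> pd.DataFrame:
    rows = []
    for v in VCF(str(path)):
        rows.append({
            "id": v.ID, "chrom": v.CHROM, "start": v.POS,
            "end": v.INFO.get("END"),
            "length": abs(v.INFO.get("SVLEN", 0)) or
                      (v.INFO.get("END") - v.POS + 1),
            "dhfc": v.INFO.get("DHFC"), "dhffc": v.INFO.get("DHFFC"),
            "dhbfc": v.INFO.get("DHBFC"), "dhsp": v.INFO.get("DHSP"),
        })
    cols = ["id", "chrom", "start", "end", "length",
            "dhfc", "dhffc", "dhbfc", "dhsp"]
    return pd.DataFrame(rows, columns=cols)


def load_bundle(bundle_dir: str | Path, qc: bool = True,
                thresholds: QCThresholds = QCThresholds()) -> CohortBundle:
    """Read a generated (or user-supplied) input bundle from disk.

    With ``qc=True`` the heterozygote re-qualification rule is applied while
    reading the VCF; the retention filter is recorded in
    ``variants["retained"]`` (dropped variants stay visible for logging)."""
    d = Path(bundle_dir)
    samples = pd.read_csv(d / "samples.tsv", sep="\t").set_index("sample_id")
    Q = np.loadtxt(d / "admixture.Q")
    if Q.ndim == 1:
        Q = Q[None, :]
    sites, dosage, hap = _read_vcf(d / "cohort.vcf", list(samples.index),
                                   qc, thresholds)
    ann = pd.read_csv(d / "annotations.tsv", sep="\t")
    ann["key"] = [variant_key(c, p, r, a) for c, p, r, a in
                  zip(ann.chrom, ann.pos, ann.ref, ann.alt)]
    picked, keys = [], []
    for key, grp in ann.groupby("key", sort=False):
        picked.append(select_transcript_consequence(
            grp.drop(columns=["key"])))
        keys.append(key)
    sel = pd.DataFrame(picked, index=pd.Index(keys, name="key"))
    sel = sel.loc[sites.index]
    evidence = pd.read_csv(d / "clinvar.tsv", sep="\t")
    evidence["key"] = [variant_key(c, p, r, a) for c, p, r, a in
                       zip(evidence.chrom, evidence.pos,
                           evidence.ref, evidence.alt)]
    ev_keys = set(evidence["key"])
    catalog = pd.read_csv(d / "genes.tsv", sep="\t").set_index("gene")
    in_gene_list = sel["gene"].isin(catalog.index)
    af = pd.to_numeric(sel["af"], errors="coerce")
    sel["retained"] = [
        bool(g) and retention_filter(
            None if np.isnan(a) else float(a), k in ev_keys)
        for g, a, k in zip(in_gene_list, af, sel.index)]
    segments = pd.read_csv(d / "local_ancestry.tsv", sep="\t")
    svs = _read_svs(d / "svs.vcf")
    pgx = pd.read_csv(d / "pgx_diplotypes.tsv", sep="\t")

    def _keys(fname, col="key"):
        f = d / fname
        if not f.exists():
            return set()
        df = pd.read_csv(f, sep="\t")
        return set(df[col]) if len(df) else set()

    in_cis = []
    f = d / "in_cis_pairs.tsv"
    if f.exists():
        df = pd.read_csv(f, sep="\t")
        in_cis = list(df.itertuples(index=False, name=None))
    return CohortBundle(
        samples=samples, Q=Q, variants=sel, dosage=dosage, hap=hap,
        evidence=evidence, catalog=catalog, segments=segments, svs=svs,
        pgx=pgx, exclusion=_keys("exclusion_list.tsv"), in_cis=in_cis,
        pgx_known=_keys("pgx_known_alleles.tsv"),
        pgx_removals=_keys("pgx_manual_removals.tsv"))
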