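"""Seeded synthetic-cohort generator with planted ground truth.

Writes a self-consistent input bundle — multi-sample VCF (GT:AD:DP:GQ),
VEP-style annotation table, ClinVar-style evidence table, gene catalog,
ADMIXTURE-style Q matrix, RFMix-msp-style local-ancestry segments, duphold-
annotated SV deletions, and pharmacogene diplotypes — plus a ``truth.json``
recording every planted quantity, so every downstream stage has a known
answer.

Model choices (see docs/methods.md for rationale):

* Ancestry proportions (Q) come from a two-component mixture: "pure"
  individuals with a single dominant component (minor mass ~ Beta(1, c),
  c = ``admixture_concentration``) and an admixed fraction with a substantial
  secondary component (Uniform(0.25, 0.5)).
* Local-ancestry tracks split each haplotype into equal blocks whose labels
  are quota-sampled from the individual's Q vector, so per-genome ancestry
  dosage matches Q to within the block resolution.
* Genotypes at planted sites are Hardy–Weinberg within ancestry with the
  allele frequency implied by the planted carrier frequency, which makes the
  f^2 at-risk-couple expectation exact.
* A small rate of spurious low-quality heterozygous calls (skewed allele
  balance or low GQ) is injected; the recorded truth is computed after the
  same re-qualification rule the pipeline applies, so truth recovery fails if
  genotype QC is skipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ANCESTRIES, CDC_TIER1_MAP, ConfigError, SimConfig
from .pgx import load_phenotype_rules
from .utils import variant_key

QC_AB_LOW, QC_AB_HIGH, QC_MIN_DP, QC_MIN_GQ = 0.20, 0.80, 5, 20

_GENE_SPACING = 2_000_000
_HOTSPOT_OFFSET = 300
_HOTSPOT_WINDOW = 25


@dataclass
class SyntheticTruth:
    """Planted/realized ground truth of a generated bundle (JSON-backed)."""

    data: dict

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "SyntheticTruth":
        return cls(json.loads(Path(path).read_text()))

    def __getitem__(self, key: str):
        return self.data[key]


def expected_arc_rate(carrier_freqs: dict[str, float]) -> float:
    """Analytic at-risk-couple rate for independent severe recessive genes:
    1 - prod_g (1 - f_g^2), with f the per-gene carrier frequency.

    Genes whose variants are all exclusion-listed must be omitted by the
    caller (they contribute no risk)."""
    prod = 1.0
    for f in carrier_freqs.values():
        if not (0.0 <= f <= 1.0):
            raise ConfigError("carrier frequency outside [0, 1]")
        prod *= 1.0 - f * f
    return 1.0 - prod


def expected_summaries(truth: SyntheticTruth) -> dict:
    """Analytic expectations derived from planted truth: per-gene carrier
    frequencies, per-ancestry ARC rate (exclusion-adjusted), hotspot list."""
    arc = {}
    for anc in ANCESTRIES:
        freqs = {g: f_by_anc[anc]
                 for g, f_by_anc in truth["arc_gene_freqs"].items()}
        arc[anc] = expected_arc_rate(freqs)
    return {
        "carrier_freq": truth["planted_carrier_freq"],
        "expected_arc": arc,
        "hotspots": truth["hotspots"],
    }


# --------------------------------------------------------------------------
# internal plan records


@dataclass
class _VariantPlan:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    is_mane: bool = True
    hgvsp: str = ""
    revel: float | None = None
    spliceai: float | None = None
    pvs1: str = ""
    plan: str = "hwe"  # hwe | chosen
    freq: dict[str, float] | None = None
    carriers: list[tuple[int, int]] | None = None  # (sample index, haplotype)
    evidence: dict | None = None
    expected_category: str = "Unclassified"
    expected_tier: str = "none"
    expected_review: bool = False
    expected_retained: bool = True
    tag: str = ""

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


def _twoplus(gene, hgvsp="", vtype="missense_variant", stars=3, n_p=4, n_lp=1):
    return {"gene": gene, "review_stars": stars, "classification": "P/LP",
            "n_p": n_p, "n_lp": n_lp, "n_vus": 0, "n_lb": 0, "n_b": 0,
            "conflicting": 0, "variant_type": vtype, "hgvsp": hgvsp}


def _benign(gene, stars=2):
    return {"gene": gene, "review_stars": stars, "classification": "B/LB",
            "n_p": 0, "n_lp": 0, "n_vus": 0, "n_lb": 2, "n_b": 3,
            "conflicting": 0, "variant_type": "missense_variant", "hgvsp": ""}


def _conflicting(gene, n_plp, n_vus):
    n_p = n_plp // 2
    return {"gene": gene, "review_stars": 1, "classification": "Conflicting",
            "n_p": n_p, "n_lp": n_plp - n_p, "n_vus": n_vus, "n_lb": 0,
            "n_b": 0, "conflicting": 1, "variant_type": "missense_variant",
            "hgvsp": ""}


# --------------------------------------------------------------------------
# generator


class _Generator:
    def __init__(self, config: SimConfig, out_dir: Path):
        config.validate()
        self.cfg = config
        self.out = Path(out_dir)
        self.rng = np.random.default_rng(config.seed)
        self.n = sum(config.n_per_ancestry.values())
        self.block_len = config.chrom_length // config.n_blocks

    # ---- samples, Q vectors, local ancestry -----------------------------

    def _make_samples(self) -> None:
        cfg, rng = self.cfg, self.rng
        anc_idx = {a: i for i, a in enumerate(ANCESTRIES)}
        planted = np.concatenate([
            np.full(cfg.n_per_ancestry[a], anc_idx[a], dtype=np.int8)
            for a in ANCESTRIES])
        n = self.n
        admixed = rng.random(n) < cfg.fraction_admixed
        Q = np.zeros((n, 3))
        secondary = np.full(n, -1, dtype=np.int8)
        for i in range(n):
            p = planted[i]
            others = [j for j in range(3) if j != p]
            if admixed[i]:
                while True:
                    m = rng.uniform(0.25, 0.5)
                    t = rng.uniform(0.0, 0.15)
                    if 1.0 - m - t > m:
                        break
                s = others[rng.integers(0, 2)]
                o = others[0] if s == others[1] else others[1]
                Q[i, p], Q[i, s], Q[i, o] = 1.0 - m - t, m, t
                secondary[i] = s
            else:
                while True:
                    eps = rng.beta(1.0, cfg.admixture_concentration)
                    if eps < 0.5:
                        break
                u = rng.uniform()
                Q[i, p] = 1.0 - eps
                Q[i, others[0]], Q[i, others[1]] = eps * u, eps * (1.0 - u)
        self_report = planted.copy()
        mism = admixed & (rng.random(n) < cfg.mismatch_prob_admixed)
        self_report[mism] = secondary[mism]
        self.planted_anc = planted
        self.admixed = admixed
        self.Q = Q
        self.assigned = np.argmax(Q, axis=1).astype(np.int8)
        self.self_report = self_report
        self.sample_ids = [f"S{i:05d}" for i in range(n)]
        self.sex = np.where(rng.random(n) < cfg.female_fraction, "F", "M")
        self.age = rng.integers(0, 86, size=n)
        # local-ancestry block labels: per-haplotype quota sampling from Q
        nb = cfg.n_blocks
        labels = np.empty((n, 2, nb), dtype=np.int8)
        for i in range(n):
            counts = self._quota(Q[i], nb)
            base = np.repeat(np.arange(3, dtype=np.int8), counts)
            for h in (0, 1):
                labels[i, h] = rng.permutation(base)
        self.blocks = labels

    @staticmethod
    def _quota(q: np.ndarray, nb: int) -> np.ndarray:
        raw = q * nb
        counts = np.floor(raw).astype(int)
        rem = nb - counts.sum()
        order = np.argsort(-(raw - counts), kind="stable")
        for k in range(rem):
            counts[order[k]] += 1
        return counts

    # ---- gene models ----------------------------------------------------

    def _make_genes(self) -> None:
        rows = []
        disease = {g.gene for g in self.cfg.planted_genes}
        roster = list(self.cfg.planted_genes)
        pgx_extra = [g for g in sorted(self.cfg.planted_pgx) if g not in disease]
        for i, g in enumerate(roster):
            chrom = "X" if g.inheritance == "XL" else "1"
            start = 5_000_000 if chrom == "X" else (i + 1) * _GENE_SPACING
            rows.append(self._gene_row(g.gene, chrom, start, g))
        base = (len(roster) + 2) * _GENE_SPACING
        for j, name in enumerate(pgx_extra):
            rows.append(self._gene_row(name, "1", base + j * _GENE_SPACING, None))
        self.genes = pd.DataFrame(rows)
        self.gene_start = dict(zip(self.genes.gene, self.genes.start))
        self.gene_chrom = dict(zip(self.genes.gene, self.genes.chrom))
        self._offset: dict[str, int] = {}

    @staticmethod
    def _gene_row(name, chrom, start, planted) -> dict:
        i = start // _GENE_SPACING
        return {
            "gene": name, "chrom": chrom, "start": start,
            "end": start + 50_000,
            "strand": planted.strand if planted else "+",
            "inheritance": planted.inheritance if planted else "AR",
            "mane_transcript": f"NM_{1000 + i}.1",
            "transcript_length": 3000 + 137 * i,
            "clinical_tx": "",
            "clingen_hi": int(planted.clingen_hi) if planted else 0,
            "pli": "" if (planted is None or planted.pli is None) else planted.pli,
            "twoplus_plp_lof_count":
                planted.twoplus_plp_lof_count if planted else 0,
            "severe": int(planted.severe) if planted else 0,
            "panels": ",".join(planted.panels) if planted else "",
            "domain": planted.domain if planted else "pharmacogene",
            "condition": planted.condition if planted else "",
            "mane_exon_start": start, "mane_exon_end": start + 2000,
        }

    def _pos(self, gene: str, offset: int | None = None) -> int:
        """Next free position in a gene (or a fixed offset from its start)."""
        if offset is not None:
            return self.gene_start[gene] + offset
        k = self._offset.get(gene, 0)
        self._offset[gene] = k + 1
        return self.gene_start[gene] + 100 + 7 * k

    # ---- variant roster -------------------------------------------------

    def _plan_variants(self) -> None:
        cfg = self.cfg
        plans: list[_VariantPlan] = []
        self.extra_evidence: list[dict] = []  # evidence-only rows (not in VCF)
        self.exclusion_keys: list[str] = []
        self.in_cis_pairs: list[tuple[str, str]] = []
        self.known_pgx_allele_keys: list[tuple[str, str]] = []
        self.pgx_manual_removals: list[str] = []
        self.pgx_lof_expected: list[str] = []

        # recurrent per-gene P/LP variants at planted carrier frequencies
        for g in cfg.planted_genes:
            pos = self._pos(g.gene, 100)
            ref, alt = ("A", "G")
            if g.variant_type == "frameshift_variant":
                ref, alt = "AT", "A"
            p = _VariantPlan(
                g.gene, self.gene_chrom[g.gene], pos, ref, alt,
                g.variant_type, hgvsp="p.Arg100Gln",
                revel=0.6 if g.variant_type == "missense_variant" else None,
                freq=dict(g.carrier_freq),
                evidence=_twoplus(g.gene, vtype=g.variant_type),
                expected_category="P/LP", expected_tier="Tier1A_TwoPlus",
                tag=f"profile:{g.gene}")
            plans.append(p)
            if g.excluded:
                self.exclusion_keys.append(p.key)

        # ancestry-specific variants (placement resolved after genotypes)
        self.specific_plans = []
        for k, sv in enumerate(cfg.planted_specific_variants):
            pos = self._pos(sv.gene, 150 + 7 * k)
            p = _VariantPlan(
                sv.gene, self.gene_chrom[sv.gene], pos, "C", "T",
                "missense_variant", revel=0.55, plan="chosen", carriers=[],
                evidence=_twoplus(sv.gene),
                expected_category="P/LP", expected_tier="Tier1A_TwoPlus",
                tag=f"specific:{sv.gene}:{sv.ancestry}")
            plans.append(p)
            self.specific_plans.append((p, sv))

        # hotspot anchors (evidence-only), benign decoys, resident missense
        self.hotspot_truth: dict[str, dict] = {}
        for hs in cfg.planted_hotspots:
            start = self.gene_start[hs.gene] + _HOTSPOT_OFFSET
            anchors = [start + j * hs.spacing for j in range(hs.n_plp)]
            benign = [start + 1 + j for j in range(hs.n_benign)]
            chrom = self.gene_chrom[hs.gene]
            for a in anchors:
                self.extra_evidence.append(
                    dict(_twoplus(hs.gene), chrom=chrom, pos=a, ref="G", alt="A"))
            for b in benign:
                self.extra_evidence.append(
                    dict(_benign(hs.gene), chrom=chrom, pos=b, ref="T", alt="C"))
            qualifies = hs.n_plp >= 3 and hs.n_benign < hs.n_plp
            self.hotspot_truth[hs.gene] = {
                "anchors": anchors, "benign": benign, "qualifies": qualifies}
            if hs.resident_revel is not None:
                p = _VariantPlan(
                    hs.gene, chrom, start + 15, "A", "G", "missense_variant",
                    hgvsp="p.Gly500Ser", revel=hs.resident_revel,
                    plan="chosen", carriers=[],
                    expected_category="VUS-FP" if (
                        qualifies and hs.resident_revel > 0.7) else "VUS",
                    tag=f"hotspot_resident:{hs.gene}")
                plans.append(p)

        if cfg.plant_classifier_exercises:
            plans.extend(self._exercise_plans())

        # pharmacogene LOF-screen exercises
        for gene, cons, off, emitted, note in (
                ("CYP2C19", "stop_gained", 200, True, "novel"),
                ("UGT1A1", "frameshift_variant", 200, False, "known_allele"),
                ("VKORC1", "stop_gained", 200, False, "outside_10"),
                ("SLCO1B1", "stop_gained", 200, False, "manual_removal"),
                ("TPMT", "stop_gained", 200, False, "no_pvs1")):
            if gene not in self.gene_start:
                continue
            ref, alt = ("AT", "A") if cons == "frameshift_variant" else ("G", "T")
            p = _VariantPlan(
                gene, self.gene_chrom[gene], self._pos(gene, 200), ref, alt,
                cons, pvs1="" if note == "no_pvs1" else "Very Strong",
                plan="chosen", carriers=[],
                expected_category="P/LP" if note != "no_pvs1" else "VUS",
                expected_tier="Tier1B" if note != "no_pvs1" else "none",
                tag=f"pgx_lof:{gene}:{note}")
            plans.append(p)
            if note == "known_allele":
                self.known_pgx_allele_keys.append((gene, p.key))
                # a known no-function allele is P/LP by the downstream rule
                # only if anchors exist; keep it un-anchored -> VUS
                p.expected_category, p.expected_tier = "VUS", "none"
                p.pvs1 = ""
            if note == "manual_removal":
                self.pgx_manual_removals.append(p.key)
            if emitted:
                self.pgx_lof_expected.append(p.key)

        self.plans = plans

    def _exercise_plans(self) -> list[_VariantPlan]:
        """Fixed-carrier variants exercising every classifier branch."""
        P: list[_VariantPlan] = []

        def chosen(gene, off, ref, alt, cons, **kw):
            p = _VariantPlan(gene, self.gene_chrom[gene],
                             self._pos(gene, off), ref, alt, cons,
                             plan="chosen", carriers=[], **kw)
            P.append(p)
            return p

        chosen("KCNQ1", 200, "A", "G", "missense_variant", revel=0.4,
               evidence=_conflicting("KCNQ1", n_plp=5, n_vus=2),
               expected_category="P/LP", expected_tier="Tier1A_Conflicting",
               tag="conflicting_high")
        chosen("MYBPC3", 200, "A", "G", "missense_variant", revel=0.5,
               evidence=_conflicting("MYBPC3", n_plp=2, n_vus=1),
               expected_category="VUS", expected_review=True,
               tag="conflicting_low")
        chosen("PRSS1", 200, "A", "G", "missense_variant", revel=0.3,
               evidence=_conflicting("PRSS1", n_plp=0, n_vus=5),
               expected_category="VUS", tag="conflicting_vus")
        # novel SNV producing a known TwoPlus amino-acid change
        p = chosen("BRCA2", 200, "C", "G", "missense_variant", revel=0.5,
                   hgvsp="p.Arg600Gln",
                   expected_category="P/LP", expected_tier="Tier1A_TwoPlus",
                   tag="novel_same_codon")
        self.extra_evidence.append(dict(
            _twoplus("BRCA2", hgvsp="p.Arg600Gln"),
            chrom=p.chrom, pos=p.pos + 1, ref="G", alt="A"))
        chosen("MLH1", 220, "C", "T", "stop_gained", pvs1="Very Strong",
               expected_category="P/LP", expected_tier="Tier1B",
               tag="tier1b_pvs1")
        # frameshift rescued by >=2 TwoPlus P/LP downstream (plus strand)
        p = chosen("BRCA2", 240, "AT", "A", "frameshift_variant",
                   expected_category="P/LP", expected_tier="Tier1B",
                   tag="tier1b_downstream")
        for d in (400, 410):
            self.extra_evidence.append(dict(
                _twoplus("BRCA2", vtype="stop_gained"),
                chrom=p.chrom, pos=self.gene_start["BRCA2"] + d,
                ref="G", alt="T"))
        # minus-strand gene: transcript-downstream anchors sit genomically 5'
        p = chosen("POLG", 240, "G", "A", "stop_gained",
                   expected_category="P/LP", expected_tier="Tier1B",
                   tag="tier1b_downstream_minus")
        for d in (150, 160):
            self.extra_evidence.append(dict(
                _twoplus("POLG", vtype="stop_gained"),
                chrom=p.chrom, pos=self.gene_start["POLG"] + d,
                ref="G", alt="T"))
        chosen("GNE", 260, "G", "T", "stop_gained", is_mane=False,
               expected_category="VUS", tag="tier1b_fail_nonmane")
        chosen("TTN", 220, "C", "A", "stop_gained", pvs1="Very Strong",
               expected_category="VUS", expected_review=True, tag="ttn_lof")
        # close-proximity frameshift pair, net length change +3
        a = chosen("SLC22A5", 220, "AT", "A", "frameshift_variant",
                   expected_category="VUS", expected_review=True,
                   tag="fs_pair_a")
        b = chosen("SLC22A5", 224, "A", "ACTGA", "frameshift_variant",
                   expected_category="VUS", expected_review=True,
                   tag="fs_pair_b")
        self.fs_pair = (a, b)
        # in-cis P/LP pair counted as one event
        c1 = chosen("GAA", 220, "C", "T", "missense_variant",
                    evidence=_twoplus("GAA"),
                    expected_category="P/LP", expected_tier="Tier1A_TwoPlus",
                    tag="cis_a")
        c2 = chosen("GAA", 229, "C", "T", "missense_variant",
                    evidence=_twoplus("GAA"),
                    expected_category="P/LP", expected_tier="Tier1A_TwoPlus",
                    tag="cis_b")
        self.in_cis_pairs.append((c1.key, c2.key))
        self.cis_pair = (c1, c2)
        chosen("GJB2", 200, "T", "C", "missense_variant", revel=0.2,
               evidence=_benign("GJB2"),
               expected_category="Unclassified", tag="benign_clinvar")
        chosen("CD36", 200, "G", "A", "synonymous_variant",
               expected_category="Unclassified", tag="unclassified_syn")
        # common missense, not in ClinVar -> dropped by the retention filter
        _ = chosen("HFE", 200, "T", "G", "missense_variant", revel=0.1,
                   expected_category="dropped", expected_retained=False,
                   tag="retention_drop")
        P[-1].plan = "hwe"
        P[-1].freq = {"CH": 0.5, "IND": 0.5, "MY": 0.5}
        # high-REVEL missense outside any hotspot stays VUS
        chosen("LDLR", 500, "A", "C", "missense_variant", revel=0.9,
               expected_category="VUS", tag="vus_outside_hotspot")
        # inside hotspot, REVEL at/below threshold or missing -> VUS
        chosen("LDLR", _HOTSPOT_OFFSET + 5, "T", "A", "missense_variant",
               revel=0.70, expected_category="VUS", tag="vus_revel_at_thresh")
        chosen("KCNQ1", _HOTSPOT_OFFSET + 8, "T", "A", "missense_variant",
               revel=None, expected_category="VUS", tag="vus_revel_missing")
        # cryptic splice branch: gene LOF count >=5 passes, ==4 or score
        # at threshold stays VUS
        chosen("BRCA1", 200, "G", "C", "intron_variant", spliceai=0.92,
               expected_category="VUS-FP", tag="vusfp_splice")
        chosen("MSH6", 200, "G", "C", "intron_variant", spliceai=0.90,
               expected_category="VUS", tag="vus_splice_lowcount")
        chosen("BRCA1", 207, "G", "C", "intron_variant", spliceai=0.80,
               expected_category="VUS", tag="vus_splice_at_thresh")
        return P

    # ---- genotype realization -------------------------------------------

    def _assign_chosen_carriers(self) -> None:
        """Pick carriers for fixed-carrier plans; ancestry-specific variants
        go only onto haplotypes whose local-ancestry block matches."""
        rng = self.rng
        anc_idx = {a: i for i, a in enumerate(ANCESTRIES)}
        specific = {id(p): sv for p, sv in self.specific_plans}
        taken_pairs: set[tuple[int, int]] = set()
        shared = {"fs_pair_a": "fs1", "fs_pair_b": "fs1",
                  "cis_a": "cis1", "cis_b": "cis1"}
        shared_carriers: dict[str, list[tuple[int, int]]] = {}
        for p in self.plans:
            if p.plan != "chosen":
                continue
            if p.tag in shared and shared[p.tag] in shared_carriers:
                p.carriers = list(shared_carriers[shared[p.tag]])
                continue
            sv = specific.get(id(p))
            if sv is not None:
                block = (p.pos - 1) // self.block_len
                a = anc_idx[sv.ancestry]
                carriers: list[tuple[int, int]] = []
                used: set[int] = set()
                for want_discordant, count in (
                        (True, sv.n_discordant),
                        (False, sv.allele_count - sv.n_discordant)):
                    cand = np.flatnonzero(
                        (self.blocks[:, 0, block] == a)
                        | (self.blocks[:, 1, block] == a))
                    if want_discordant:
                        # discordant carriers model cryptic admixture: an
                        # appreciable component of the variant's ancestry
                        mask = (self.assigned != a) & (self.Q[:, a] >= 0.10)
                    else:
                        mask = self.assigned == a
                    cand = [s for s in cand if mask[s] and s not in used]
                    pick = rng.choice(len(cand), size=min(count, len(cand)),
                                      replace=False) if cand else []
                    for ci in sorted(int(x) for x in np.atleast_1d(pick)):
                        s = cand[ci]
                        h = 0 if self.blocks[s, 0, block] == a else 1
                        carriers.append((int(s), int(h)))
                        used.add(s)
                p.carriers = carriers
            else:
                n_car = 5 if p.tag.startswith("hotspot") else 3
                cand = [s for s in range(self.n)]
                pick = rng.choice(self.n, size=n_car, replace=False)
                p.carriers = [(int(s), int(rng.integers(0, 2)))
                              for s in sorted(pick)]
            if p.tag in shared:
                shared_carriers[shared[p.tag]] = list(p.carriers)
            taken_pairs.update(p.carriers)

    def _realize(self) -> None:
        """Draw genotypes + call metrics, apply the QC rule to get truth."""
        cfg, rng, n = self.cfg, self.rng, self.n
        male = self.sex == "M"
        self.dos_raw = np.zeros((len(self.plans), n), dtype=np.int8)
        self.hap = np.zeros((len(self.plans), n, 2), dtype=np.int8)
        self.ad_ref = np.zeros((len(self.plans), n), dtype=np.int32)
        self.ad_alt = np.zeros((len(self.plans), n), dtype=np.int32)
        self.dp = np.zeros((len(self.plans), n), dtype=np.int32)
        self.gq = np.zeros((len(self.plans), n), dtype=np.int32)
        anc_of = self.planted_anc
        for vi, p in enumerate(self.plans):
            dos = np.zeros(n, dtype=np.int8)
            if p.plan == "hwe":
                f = np.array([p.freq[a] for a in ANCESTRIES])
                pa = 1.0 - np.sqrt(1.0 - f)
                p_i = pa[anc_of]
                if p.chrom == "X":
                    fem = ~male
                    dos[fem] = rng.binomial(2, pa[anc_of[fem]])
                    # male hemizygote: carrier with probability f, written
                    # as a homozygous diploid call
                    dos[male] = 2 * rng.binomial(1, f[anc_of[male]])
                else:
                    dos = rng.binomial(2, p_i).astype(np.int8)
                het = dos == 1
                hap_pick = rng.integers(0, 2, size=n)
                self.hap[vi, het, 0] = (hap_pick[het] == 0)
                self.hap[vi, het, 1] = (hap_pick[het] == 1)
                self.hap[vi, dos == 2] = 1
            else:
                for s, h in p.carriers or []:
                    dos[s] = 1
                    self.hap[vi, s, h] = 1
            # spurious low-quality het calls on reference individuals
            if cfg.bad_call_rate > 0 and p.plan == "hwe":
                bad = (dos == 0) & (rng.random(n) < cfg.bad_call_rate)
            else:
                bad = np.zeros(n, dtype=bool)
            dos[bad] = 1
            self.hap[vi, bad, 0] = 1
            self.dos_raw[vi] = dos
            # call metrics
            dp = np.maximum(rng.poisson(32, size=n), 10)
            alt = np.zeros(n, dtype=np.int64)
            het = dos == 1
            alt[het] = rng.binomial(dp[het], 0.5)
            alt[dos == 2] = dp[dos == 2]
            gq = rng.integers(60, 100, size=n)
            # two failure modes for the injected bad calls
            if bad.any():
                mode = rng.random(n) < 0.5
                ab_bad = bad & mode
                gq_bad = bad & ~mode
                dp[ab_bad] = 25
                alt[ab_bad] = 2       # allele balance 0.08
                dp[gq_bad] = 25
                alt[gq_bad] = 12
                gq[gq_bad] = 12
            self.ad_alt[vi] = alt
            self.ad_ref[vi] = dp - alt
            self.dp[vi] = dp
            self.gq[vi] = gq
        # re-qualification truth: het calls failing AB/DP/GQ become no-call
        ab_den = self.ad_ref + self.ad_alt
        with np.errstate(divide="ignore", invalid="ignore"):
            ab = np.where(ab_den > 0, self.ad_alt / np.maximum(ab_den, 1), -1.0)
        het = self.dos_raw == 1
        fail = het & ~((ab >= QC_AB_LOW) & (ab <= QC_AB_HIGH)
                       & (self.dp >= QC_MIN_DP) & (self.gq >= QC_MIN_GQ))
        self.dos_qc = self.dos_raw.astype(np.int8).copy()
        self.dos_qc[fail] = -1
        self.hap_qc = self.hap.copy()
        self.hap_qc[fail] = 0
        self.af = self.dos_raw.clip(min=0).sum(axis=1) / (2.0 * n)

    # ---- truth ----------------------------------------------------------

    def _build_truth(self) -> SyntheticTruth:
        cfg = self.cfg
        anc_idx = {a: i for i, a in enumerate(ANCESTRIES)}
        plp_rows = [vi for vi, p in enumerate(self.plans)
                    if p.expected_category == "P/LP"]
        carrier_truth: dict[str, dict[str, int]] = {}
        genes_of = {}
        for vi in plp_rows:
            genes_of.setdefault(self.plans[vi].gene, []).append(vi)
        for gene, vis in genes_of.items():
            carried = (self.dos_qc[vis] > 0).any(axis=0)
            carrier_truth[gene] = {
                a: int(carried[self.planted_anc == anc_idx[a]].sum())
                for a in ANCESTRIES}
        # panel prevalence (>=1 P/LP in panel genes), overall and <=50y
        prevalence = {}
        for panel in ("acmg_sf_v2", "acmg_sf_v3"):
            panel_genes = {g.gene for g in cfg.planted_genes
                           if panel in g.panels}
            vis = [vi for vi in plp_rows if self.plans[vi].gene in panel_genes]
            flag = (self.dos_qc[vis] > 0).any(axis=0) if vis else \
                np.zeros(self.n, bool)
            prevalence[panel] = int(flag.sum())
        spec_truth = []
        for p, sv in self.specific_plans:
            hap = self.hap_qc[self.plans.index(p)]
            carriers = np.flatnonzero(hap.any(axis=1))
            disc = [self.sample_ids[s] for s in carriers
                    if ANCESTRIES[self.assigned[s]] != sv.ancestry]
            spec_truth.append({
                "key": p.key, "gene": p.gene, "ancestry": sv.ancestry,
                "allele_count": int(hap.sum()),
                "carriers": [self.sample_ids[s] for s in carriers],
                "discordant_carriers": disc,
            })
        arc_gene_freqs = {
            g.gene: g.carrier_freq for g in cfg.planted_genes
            if g.severe and g.inheritance == "AR" and not g.excluded}
        rules = load_phenotype_rules()
        pgx_expected: dict[str, dict[str, float]] = {}
        for gene, alleles in cfg.planted_pgx.items():
            pgx_expected[gene] = {}
            for anc in ANCESTRIES:
                pa = {al.name: al.freq[anc] for al in alleles}
                fn = {al.name: al.function for al in alleles}
                prob = 0.0
                names = list(pa)
                for i, a1 in enumerate(names):
                    for a2 in names[i:]:
                        w = pa[a1] * pa[a2] * (1 if a1 == a2 else 2)
                        pheno, actionable = rules.lookup(gene, fn[a1], fn[a2])
                        if actionable:
                            prob += w
                pgx_expected[gene][anc] = prob
        tier1_pgx_prob = {}
        for cond, m in CDC_TIER1_MAP.items():
            gene = m["pgx_gene"]
            if gene not in cfg.planted_pgx:
                continue
            tier1_pgx_prob[cond] = {}
            for anc in ANCESTRIES:
                alleles = cfg.planted_pgx[gene]
                pa = {al.name: al.freq[anc] for al in alleles}
                fn = {al.name: al.function for al in alleles}
                prob = 0.0
                names = list(pa)
                for i, a1 in enumerate(names):
                    for a2 in names[i:]:
                        w = pa[a1] * pa[a2] * (1 if a1 == a2 else 2)
                        pheno, _ = rules.lookup(gene, fn[a1], fn[a2])
                        if pheno in m["pgx_phenotypes"]:
                            prob += w
                tier1_pgx_prob[cond][anc] = prob
        truth = {
            "seed": cfg.seed,
            "n_per_ancestry": dict(cfg.n_per_ancestry),
            "assigned_counts": {a: int((self.assigned == anc_idx[a]).sum())
                                for a in ANCESTRIES},
            "mismatched_samples": [self.sample_ids[i]
                                   for i in np.flatnonzero(
                                       self.self_report != self.assigned)],
            "admixed_samples": [self.sample_ids[i]
                                for i in np.flatnonzero(self.admixed)],
            "planted_carrier_freq": {
                g.gene: g.carrier_freq for g in cfg.planted_genes},
            "carrier_truth": carrier_truth,
            "prevalence_carriers": prevalence,
            "classification": {
                p.key: {"category": p.expected_category,
                        "tier": p.expected_tier,
                        "review": p.expected_review, "tag": p.tag}
                for p in self.plans if p.expected_retained},
            "retention_dropped": [p.key for p in self.plans
                                  if not p.expected_retained],
            "hotspots": self.hotspot_truth,
            "specific_variants": spec_truth,
            "arc_gene_freqs": arc_gene_freqs,
            "exclusion_keys": list(self.exclusion_keys),
            "expected_arc": {
                anc: expected_arc_rate(
                    {g: f[anc] for g, f in arc_gene_freqs.items()})
                for anc in ANCESTRIES},
            "pgx_expected_actionable": pgx_expected,
            "tier1_pgx_prob": tier1_pgx_prob,
            "pgx_lof_expected": list(self.pgx_lof_expected),
            "sv_pass": list(getattr(self, "sv_pass", [])),
        }
        return SyntheticTruth(truth)

    # ---- writers --------------------------------------------------------

    def _write_vcf(self) -> None:
        order = sorted(range(len(self.plans)),
                       key=lambda vi: (self.plans[vi].chrom,
                                       self.plans[vi].pos))
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID=1,length={self.cfg.chrom_length}>",
            "##contig=<ID=X,length=156040895>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
            '"Allelic depths">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description='
            '"Genotype quality">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.sample_ids),
        ]
        gt_str = {(0, 0): "0|0", (1, 0): "1|0", (0, 1): "0|1", (1, 1): "1|1"}
        for vi in order:
            p = self.plans[vi]
            h = self.hap[vi]
            cells = [
                f"{gt_str[(h[s, 0], h[s, 1])]}:"
                f"{self.ad_ref[vi, s]},{self.ad_alt[vi, s]}:"
                f"{self.dp[vi, s]}:{self.gq[vi, s]}"
                for s in range(self.n)]
            lines.append(
                f"{p.chrom}\t{p.pos}\t.\t{p.ref}\t{p.alt}\t100\tPASS\t.\t"
                "GT:AD:DP:GQ\t" + "\t".join(cells))
        (self.out / "cohort.vcf").write_text("\n".join(lines) + "\n")

    def _write_tables(self) -> None:
        out = self.out
        ann_rows = []
        for vi, p in enumerate(self.plans):
            ann_rows.append({
                "chrom": p.chrom, "pos": p.pos, "ref": p.ref, "alt": p.alt,
                "gene": p.gene,
                "transcript": self.genes.set_index("gene").loc[
                    p.gene, "mane_transcript"] if p.is_mane
                else f"NM_alt_{p.gene}.1",
                "is_mane": int(p.is_mane),
                "consequence": p.consequence,
                "hgvsc": f"c.{p.pos - self.gene_start[p.gene]}{p.ref}>{p.alt}",
                "hgvsp": p.hgvsp,
                "revel": "" if p.revel is None else p.revel,
                "spliceai_max": "" if p.spliceai is None else p.spliceai,
                "primateai": "",
                "af": round(float(self.af[vi]), 6),
                "pvs1": p.pvs1,
            })
        pd.DataFrame(ann_rows).to_csv(out / "annotations.tsv", sep="\t",
                                      index=False)
        ev_rows = []
        for p in self.plans:
            if p.evidence is not None:
                ev_rows.append(dict(p.evidence, chrom=p.chrom, pos=p.pos,
                                    ref=p.ref, alt=p.alt))
        ev_rows.extend(self.extra_evidence)
        cols = ["chrom", "pos", "ref", "alt", "gene", "review_stars",
                "classification", "n_p", "n_lp", "n_vus", "n_lb", "n_b",
                "conflicting", "variant_type", "hgvsp"]
        pd.DataFrame(ev_rows)[cols].to_csv(out / "clinvar.tsv", sep="\t",
                                           index=False)
        self.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        pd.DataFrame({
            "sample_id": self.sample_ids,
            "self_reported": [ANCESTRIES[i] for i in self.self_report],
            "sex": self.sex,
            "age": self.age,
        }).to_csv(out / "samples.tsv", sep="\t", index=False)
        # ADMIXTURE-style .Q: whitespace-delimited, no header, row per sample
        with open(out / "admixture.Q", "w") as fh:
            for i in range(self.n):
                q1 = round(self.Q[i, 0], 9)
                q2 = round(self.Q[i, 1], 9)
                q3 = 1.0 - q1 - q2
                fh.write(f"{q1:.9f} {q2:.9f} {q3:.9f}\n")
        # RFMix-msp-style segments (merged constant-label runs)
        with open(out / "local_ancestry.tsv", "w") as fh:
            fh.write("sample_id\thaplotype\tchrom\tstart\tend\tancestry\n")
            bl = self.block_len
            for i, sid in enumerate(self.sample_ids):
                for h in (0, 1):
                    labels = self.blocks[i, h]
                    start_b = 0
                    for b in range(1, self.cfg.n_blocks + 1):
                        if b == self.cfg.n_blocks or labels[b] != labels[start_b]:
                            s = start_b * bl + 1
                            e = b * bl if b < self.cfg.n_blocks \
                                else self.cfg.chrom_length
                            fh.write(f"{sid}\t{h}\t1\t{s}\t{e}\t"
                                     f"{ANCESTRIES[labels[start_b]]}\n")
                            start_b = b
        pd.DataFrame({"key": self.exclusion_keys}).to_csv(
            out / "exclusion_list.tsv", sep="\t", index=False)
        pd.DataFrame(self.in_cis_pairs, columns=["key1", "key2"]).to_csv(
            out / "in_cis_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(self.known_pgx_allele_keys,
                     columns=["gene", "key"]).to_csv(
            out / "pgx_known_alleles.tsv", sep="\t", index=False)
        pd.DataFrame({"key": self.pgx_manual_removals}).to_csv(
            out / "pgx_manual_removals.tsv", sep="\t", index=False)

    def _write_pgx(self) -> None:
        rng, cfg = self.rng, self.cfg
        anc_of = self.planted_anc
        rows = []
        for gene in sorted(cfg.planted_pgx):
            alleles = cfg.planted_pgx[gene]
            names = [a.name for a in alleles]
            fn = {a.name: a.function for a in alleles}
            probs = np.array([[a.freq[anc] for a in alleles]
                              for anc in ANCESTRIES])
            cum = probs.cumsum(axis=1)
            for draw in (0, 1):
                u = rng.random(self.n)
                idx = (u[:, None] > cum[anc_of]).sum(axis=1)
                if draw == 0:
                    a1 = idx
                else:
                    a2 = idx
            for i, sid in enumerate(self.sample_ids):
                rows.append({
                    "sample_id": sid, "gene": gene,
                    "allele1": names[a1[i]], "allele2": names[a2[i]],
                    "function1": fn[names[a1[i]]],
                    "function2": fn[names[a2[i]]]})
        cols = ["sample_id", "gene", "allele1", "allele2",
                "function1", "function2"]
        pd.DataFrame(rows, columns=cols).to_csv(
            self.out / "pgx_diplotypes.tsv", sep="\t", index=False)

    def _write_svs(self) -> None:
        if not self.cfg.plant_svs:
            (self.out / "svs.vcf").write_text(_sv_header() + "\n")
            self.sv_pass = []
            return
        gs = self.gene_start

        def rec(name, gene, offset, length, dhfc, dhffc, dhbfc, dhsp):
            start = (gs[gene] + offset) if gene else 50_000_000
            return (name, start, length, dhfc, dhffc, dhbfc, dhsp)

        records = [
            rec("DEL1", "LDLR", 500, 3000, 0.5, 0.45, 0.5, 2),
            rec("DEL2", "HBB", 500, 400, 0.5, 0.5, 0.5, 2),
            rec("DEL3", "BRCA1", 500, 5000, 0.5, 0.5, 0.5, 1),
            rec("DEL4", "DUOX2", 500, 3000, 0.5, 0.5, 0.5, 3),
            rec("DEL5", None, 0, 3000, 0.5, 0.5, 0.5, 2),
            rec("DEL6", "MLH1", 500, 3000, 0.75, 0.5, 0.5, 2),
            rec("DEL7", "CFTR", 500, 12_000_000, 0.5, 0.5, 0.5, 2),
            rec("DEL8", "BRCA1", 100, 8000, 0.6, 0.55, 0.65, 4),
        ]
        self.sv_pass = ["DEL1", "DEL8"]
        lines = [_sv_header()]
        for name, start, length, dhfc, dhffc, dhbfc, dhsp in records:
            end = start + length - 1
            lines.append(
                f"1\t{start}\t{name}\tN\t<DEL>\t100\tPASS\t"
                f"SVTYPE=DEL;END={end};SVLEN=-{length};DHFC={dhfc};"
                f"DHFFC={dhffc};DHBFC={dhbfc};DHSP={dhsp}")
        (self.out / "svs.vcf").write_text("\n".join(lines) + "\n")

    # ---- driver ---------------------------------------------------------

    def run(self) -> SyntheticTruth:
        self.out.mkdir(parents=True, exist_ok=True)
        self._make_samples()
        self._make_genes()
        self._plan_variants()
        self._assign_chosen_carriers()
        self._realize()
        self._write_vcf()
        self._write_svs()
        self._write_tables()
        self._write_pgx()
        truth = self._build_truth()
        truth.save(self.out / "truth.json")
        return truth


def _sv_header() -> str:
    return "\n".join([
        "##fileformat=VCFv4.2",
        "##contig=<ID=1,length=250000000>",
        '##ALT=<ID=DEL,Description="Deletion">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=DHFC,Number=1,Type=Float,Description='
        '"duphold depth fold-change">',
        '##INFO=<ID=DHFFC,Number=1,Type=Float,Description='
        '"duphold depth fold-change (flank)">',
        '##INFO=<ID=DHBFC,Number=1,Type=Float,Description='
        '"duphold depth fold-change (bins)">',
        '##INFO=<ID=DHSP,Number=1,Type=Integer,Description='
        '"split-read support">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ])


def generate_cohort(config: SimConfig, out_dir: str | Path) -> SyntheticTruth:
    """Generate the full synthetic input bundle under ``out_dir``.

    Identical ``config`` (including seed) yields byte-identical files.
    Returns the planted/realized truth, which is also saved as
    ``out_dir/truth.json``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and not out_dir.is_dir():
        raise OSError(f"output path {out_dir} is not a directory")
    return _Generator(config, out_dir).run()
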