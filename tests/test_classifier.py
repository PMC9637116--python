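"""Classification rule cascade: evidence tiers, LOF rules, the hotspot
statistic, VUS-FP promotion, cohort-level behaviour and the gross-deletion
filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortscreen.classifier import (ClassifierConfig, EvidenceIndex,
                                     SVDeletion, classify_all,
                                     classify_variant, detect_hotspots,
                                     filter_gross_deletion)
from tests.conftest import hotspot_oracle

CFG = ClassifierConfig()


def make_evidence(rows):
    cols = ["key", "chrom", "pos", "ref", "alt", "gene", "review_stars",
            "classification", "n_p", "n_lp", "n_vus", "n_lb", "n_b",
            "conflicting", "variant_type", "hgvsp"]
    df = pd.DataFrame(rows, columns=cols)
    return df


def ev_row(key, gene, pos, stars=3, cls="P/LP", n_p=4, n_lp=1, n_vus=0,
           n_lb=0, n_b=0, conflicting=0, vtype="missense_variant", hgvsp=""):
    c, p, r, a = key.split(":")
    return [key, c, int(p), r, a, gene, stars, cls, n_p, n_lp, n_vus, n_lb,
            n_b, conflicting, vtype, hgvsp]


def make_catalog(genes=("GENE1",), strand="+", lof_count=0):
    return pd.DataFrame({
        "gene": list(genes), "chrom": "1", "strand": strand,
        "inheritance": "AD", "mane_transcript": "NM_1.1",
        "clinical_tx": "", "twoplus_plp_lof_count": lof_count,
        "severe": 0, "panels": "", "clingen_hi": 0, "pli": "",
        "mane_exon_start": 100, "mane_exon_end": 2100,
    }).set_index("gene")


def make_variant(key="1:500:A:G", gene="GENE1", consequence="missense_variant",
                 hgvsp="", revel=None, spliceai=None, pvs1="", is_mane=1,
                 transcript="NM_1.1"):
    c, p, r, a = key.split(":")
    return pd.Series({
        "chrom": c, "pos": int(p), "ref": r, "alt": a, "gene": gene,
        "transcript": transcript, "is_mane": is_mane,
        "consequence": consequence, "hgvsp": hgvsp, "revel": revel,
        "spliceai_max": spliceai, "pvs1": pvs1, "af": 0.001,
    }, name=key)


def classify(variant, evidence_rows=(), catalog=None, cfg=CFG):
    idx = EvidenceIndex(make_evidence(list(evidence_rows)), cfg)
    return classify_variant(variant, catalog if catalog is not None
                            else make_catalog(), idx, cfg)


# ---- Tier1A evidence rules ------------------------------------------------

def test_twoplus_plp_is_tier1a():
    v = make_variant()
    res = classify(v, [ev_row(v.name, "GENE1", 500)])
    assert (res.category, res.tier) == ("P/LP", "Tier1A_TwoPlus")


@pytest.mark.parametrize("n_p, n_lp, expect", [
    (3, 2, ("P/LP", "Tier1A_Conflicting", False)),   # >=4 P/LP submissions
    (4, 0, ("P/LP", "Tier1A_Conflicting", False)),
    (1, 1, ("VUS", "none", True)),                   # 1-3: manual curation
    (1, 0, ("VUS", "none", True)),
])
def test_conflicting_submission_rules(n_p, n_lp, expect):
    v = make_variant()
    res = classify(v, [ev_row(v.name, "GENE1", 500, stars=1,
                              cls="Conflicting", n_p=n_p, n_lp=n_lp,
                              conflicting=1)])
    assert (res.category, res.tier, res.needs_manual_review) == expect


def test_conflicting_with_four_vus_submissions_is_vus():
    v = make_variant()
    res = classify(v, [ev_row(v.name, "GENE1", 500, stars=1,
                              cls="Conflicting", n_p=0, n_lp=0, n_vus=4,
                              conflicting=1)])
    assert res.category == "VUS" and not res.needs_manual_review


def test_novel_snv_with_known_codon_change_is_plp():
    v = make_variant(key="1:500:A:G", hgvsp="p.Arg100Gln")
    ev = [ev_row("1:501:G:A", "GENE1", 501, hgvsp="p.Arg100Gln")]
    res = classify(v, ev)
    assert (res.category, res.tier) == ("P/LP", "Tier1A_TwoPlus")
    # an indel with the same annotation does not use the SNV rule
    v2 = make_variant(key="1:500:AT:A", hgvsp="p.Arg100Gln",
                      consequence="inframe_deletion")
    assert classify(v2, ev).category == "VUS"


def test_benign_aggregate_is_unclassified():
    v = make_variant()
    res = classify(v, [ev_row(v.name, "GENE1", 500, stars=2, cls="B/LB")])
    assert res.category == "Unclassified"


# ---- Tier1B LOF rules -----------------------------------------------------

def test_lof_with_very_strong_pvs1_is_tier1b():
    v = make_variant(consequence="stop_gained", pvs1="Very Strong")
    res = classify(v)
    assert (res.category, res.tier) == ("P/LP", "Tier1B")


@pytest.mark.parametrize("strand, anchor_pos, expect_plp", [
    ("+", (600, 700), True),    # downstream = larger genomic position
    ("+", (300, 400), False),   # anchors upstream
    ("-", (300, 400), True),    # minus strand: downstream = smaller position
    ("-", (600, 700), False),
])
def test_lof_downstream_anchor_rule_is_strand_aware(strand, anchor_pos,
                                                    expect_plp):
    v = make_variant(consequence="frameshift_variant",
                     key="1:500:AT:A")
    ev = [ev_row(f"1:{p}:G:T", "GENE1", p, vtype="stop_gained")
          for p in anchor_pos]
    res = classify(v, ev, make_catalog(strand=strand))
    assert (res.category == "P/LP") is expect_plp
    if expect_plp:
        assert res.tier == "Tier1B"


def test_single_downstream_anchor_is_insufficient():
    v = make_variant(consequence="stop_gained")
    res = classify(v, [ev_row("1:600:G:T", "GENE1", 600)])
    assert res.category == "VUS"


def test_lof_on_non_mane_transcript_is_not_tier1b():
    v = make_variant(consequence="stop_gained", is_mane=0,
                     transcript="NM_alt.1", pvs1="Very Strong")
    assert classify(v).category == "VUS"


def test_lof_in_gene_absent_from_catalog_is_unclassified():
    v = make_variant(gene="NOSUCH", consequence="stop_gained")
    assert classify(v).category == "Unclassified"


def test_ttn_truncating_always_needs_manual_review():
    v = make_variant(gene="TTN", consequence="stop_gained",
                     pvs1="Very Strong")
    res = classify(v, catalog=make_catalog(genes=("TTN",)))
    assert res.category == "VUS" and res.needs_manual_review


# ---- hotspots -------------------------------------------------------------

def test_hotspot_three_plp_within_window():
    windows = detect_hotspots([100, 110, 120], [])
    assert any(s <= 115 <= e for s, e in windows)   # window 100-124 holds 3
    assert not any(s <= 90 <= e for s, e in windows)


def test_hotspot_needs_more_than_two_plp():
    assert detect_hotspots([100, 200], []) == []
    assert detect_hotspots([], []) == []


def test_hotspot_benign_majority_rule():
    # the window [100, 124] itself fails (3 benign not < 3 P/LP) ...
    assert (100, 124) not in detect_hotspots([100, 110, 120],
                                             [101, 111, 121])
    # ... and with a benign shadowing every P/LP no window qualifies at all
    assert detect_hotspots([100, 110, 120], [100, 110, 120]) == []
    assert detect_hotspots([100, 110, 120], [101, 111]) != []


def test_hotspot_matches_exhaustive_scan_on_random_sets():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n_p = int(rng.integers(0, 200))
        n_b = int(rng.integers(0, 50))
        plp = sorted(set(rng.integers(1000, 3000, size=n_p).tolist()))
        blb = sorted(set(rng.integers(1000, 3000, size=n_b).tolist()))
        assert detect_hotspots(plp, blb) == hotspot_oracle(plp, blb)


@given(st.sets(st.integers(0, 400), max_size=30),
       st.sets(st.integers(0, 400), max_size=15),
       st.integers(0, 400))
@settings(max_examples=60, derandomize=True)
def test_hotspot_monotone_in_plp_evidence(plp, blb, extra):
    """Adding a TwoPlus P/LP position never removes a qualifying window."""
    before = set(detect_hotspots(sorted(plp), sorted(blb)))
    after = set(detect_hotspots(sorted(plp | {extra}), sorted(blb)))
    assert before <= after


# ---- VUS-FP ---------------------------------------------------------------

def hotspot_ev(gene="GENE1"):
    return [ev_row(f"1:{p}:G:T", gene, p) for p in (490, 500, 510)]


@pytest.mark.parametrize("revel, expect", [
    (0.80, "VUS-FP"),
    (0.71, "VUS-FP"),
    (0.70, "VUS"),       # strict > 0.7
    (None, "VUS"),       # missing score: stays VUS
])
def test_missense_revel_hotspot_rule(revel, expect):
    v = make_variant(key="1:505:A:G", revel=revel)
    assert classify(v, hotspot_ev()).category == expect


def test_high_revel_outside_hotspot_stays_vus():
    v = make_variant(key="1:900:A:G", revel=0.95)
    assert classify(v, hotspot_ev()).category == "VUS"


@pytest.mark.parametrize("spliceai, lof_count, expect", [
    (0.9, 5, "VUS-FP"),
    (0.9, 4, "VUS"),     # gene LOF count below 5
    (0.8, 5, "VUS"),     # strict > 0.8
])
def test_cryptic_splice_rule(spliceai, lof_count, expect):
    v = make_variant(consequence="intron_variant", spliceai=spliceai)
    res = classify(v, catalog=make_catalog(lof_count=lof_count))
    assert res.category == expect


@given(r1=st.floats(0.0, 1.0), r2=st.floats(0.0, 1.0))
@settings(max_examples=100, derandomize=True)
def test_raising_revel_never_demotes(r1, r2):
    lo, hi = sorted((r1, r2))
    v_lo = make_variant(key="1:505:A:G", revel=lo)
    v_hi = make_variant(key="1:505:A:G", revel=hi)
    c_lo = classify(v_lo, hotspot_ev()).category
    c_hi = classify(v_hi, hotspot_ev()).category
    assert not (c_lo == "VUS-FP" and c_hi == "VUS")


# ---- cohort-level ---------------------------------------------------------

def _mini_table(rows):
    df = pd.DataFrame(rows)
    df.index = [f"{c}:{p}:{r}:{a}" for c, p, r, a in
                zip(df.chrom, df.pos, df.ref, df.alt)]
    df.index.name = "key"
    df["retained"] = True
    return df


def test_close_frameshift_pair_in_frame_flags_review():
    rows = [
        dict(chrom="1", pos=500, ref="AT", alt="A", gene="G1",
             transcript="NM_1.1", is_mane=1,
             consequence="frameshift_variant", hgvsp="", revel=None,
             spliceai_max=None, pvs1="", af=0.001),
        dict(chrom="1", pos=504, ref="A", alt="ACTGA", gene="G1",
             transcript="NM_1.1", is_mane=1,
             consequence="frameshift_variant", hgvsp="", revel=None,
             spliceai_max=None, pvs1="", af=0.001),
    ]
    variants = _mini_table(rows)
    dosage = np.array([[1, 0], [1, 0]], dtype=np.int8)  # same sample carries
    catalog = make_catalog(genes=("G1",))
    out = classify_all(variants, dosage, catalog, make_evidence([]))
    assert (out["category"] == "VUS").all()
    assert out["needs_manual_review"].all()
    # net -1+4 = +3 in-frame; without co-occurrence no flag
    dosage2 = np.array([[1, 0], [0, 1]], dtype=np.int8)
    out2 = classify_all(variants, dosage2, catalog, make_evidence([]))
    assert not out2["needs_manual_review"].any()


def test_classification_total_and_mutually_exclusive_on_fuzzed_tables():
    rng = np.random.default_rng(99)
    consequences = ["missense_variant", "stop_gained", "frameshift_variant",
                    "synonymous_variant", "intron_variant",
                    "splice_region_variant", "inframe_deletion"]
    catalog = make_catalog(genes=("G1", "G2", "TTN"), lof_count=5)
    for _ in range(25):
        n = int(rng.integers(1, 30))
        rows, ev_rows = [], []
        for i in range(n):
            pos = int(rng.integers(100, 2000))
            ref, alt = ("AT", "A") if rng.random() < 0.3 else ("A", "G")
            key = f"1:{pos}:{ref}:{alt}"
            rows.append(dict(
                chrom="1", pos=pos, ref=ref, alt=alt,
                gene=str(rng.choice(["G1", "G2", "TTN"])),
                transcript="NM_1.1", is_mane=int(rng.random() < 0.9),
                consequence=str(rng.choice(consequences)),
                hgvsp="", revel=float(rng.random()) if rng.random() < 0.5
                else None,
                spliceai_max=float(rng.random()) if rng.random() < 0.3
                else None,
                pvs1="Very Strong" if rng.random() < 0.2 else "",
                af=float(rng.random() * 0.04)))
            if rng.random() < 0.4:
                ev_rows.append(ev_row(
                    key, rows[-1]["gene"], pos,
                    stars=int(rng.integers(0, 4)),
                    cls=str(rng.choice(["P/LP", "VUS", "B/LB",
                                        "Conflicting"])),
                    n_p=int(rng.integers(0, 6)),
                    conflicting=int(rng.random() < 0.5)))
        variants = _mini_table(rows)
        variants = variants[~variants.index.duplicated()]
        dosage = rng.integers(0, 2, size=(len(variants), 5)).astype(np.int8)
        out = classify_all(variants, dosage, catalog,
                           make_evidence(ev_rows))
        assert set(out.index) == set(variants.index)
        assert out["category"].isin(
            ["P/LP", "VUS-FP", "VUS", "Unclassified"]).all()
        assert ((out["tier"] != "none") == (out["category"] == "P/LP")).all()


def test_classification_order_independent(tiny):
    bundle = tiny["bundle"]
    perm = np.random.default_rng(1).permutation(len(bundle.variants))
    shuffled = bundle.variants.iloc[perm]
    out1 = classify_all(bundle.variants, bundle.dosage, bundle.catalog,
                        bundle.evidence)
    out2 = classify_all(shuffled, bundle.dosage[perm], bundle.catalog,
                        bundle.evidence)
    pd.testing.assert_frame_equal(out1.sort_index(), out2.sort_index())


def test_planted_classification_truth_recovered_exactly(tiny):
    """Sensitivity 1 on planted truth: every planted variant lands in its
    expected category/tier, and retention-dropped variants never surface."""
    classes = tiny["result"].classes
    for key, exp in tiny["truth"]["classification"].items():
        got = classes.loc[key]
        assert got["category"] == exp["category"], (key, exp["tag"])
        assert got["tier"] == exp["tier"], (key, exp["tag"])
        assert bool(got["needs_manual_review"]) == exp["review"], exp["tag"]
    for key in tiny["truth"]["retention_dropped"]:
        assert key not in classes.index


def test_manual_override_table_applies():
    v = make_variant()
    variants = _mini_table([dict(
        chrom="1", pos=500, ref="A", alt="G", gene="GENE1",
        transcript="NM_1.1", is_mane=1, consequence="missense_variant",
        hgvsp="", revel=None, spliceai_max=None, pvs1="", af=0.001)])
    ev = make_evidence([ev_row(v.name, "GENE1", 500, stars=1,
                               cls="Conflicting", n_p=2, n_lp=0,
                               conflicting=1)])
    overrides = pd.DataFrame({"key": [v.name], "category": ["P/LP"],
                              "tier": ["Tier1A_Conflicting"]})
    out = classify_all(variants, np.zeros((1, 2), np.int8),
                       make_catalog(), ev, overrides=overrides)
    assert out.loc[v.name, "category"] == "P/LP"


# ---- gross deletions ------------------------------------------------------

def _sv(start=100, length=3000, dhfc=0.5, dhffc=0.5, dhbfc=0.5, dhsp=2):
    return SVDeletion("1", start, start + length - 1, dhfc, dhffc, dhbfc,
                      dhsp)


@pytest.mark.parametrize("sv, ok", [
    (_sv(), True),
    (_sv(length=400), False),                  # below 500 bp
    (_sv(length=500), True),                   # inclusive lower bound
    (_sv(length=10_000_000), True),            # inclusive upper bound
    (_sv(length=10_000_001), False),
    (_sv(dhsp=1), False),                      # strict DHSP > 1
    (_sv(dhfc=0.7), False),                    # strict < 0.7
    (_sv(dhffc=0.9), False),
])
def test_gross_deletion_filter_thresholds(sv, ok):
    catalog = make_catalog()
    catalog["clingen_hi"] = 1                  # make GENE1 LOFi
    got, gene, reasons = filter_gross_deletion(sv, catalog)
    assert got is ok
    if ok:
        assert gene == "GENE1"


def test_gross_deletion_requires_lofi_mane_exon_overlap():
    catalog = make_catalog()                   # GENE1 not LOFi
    ok, gene, reasons = filter_gross_deletion(_sv(), catalog)
    assert not ok and "no_lofi_mane_exon_overlap" in reasons
    catalog["clingen_hi"] = 1
    ok, _, _ = filter_gross_deletion(_sv(start=5000), catalog)
    assert not ok                              # beyond the exon interval


def test_planted_sv_truth_recovered(tiny):
    svs = tiny["result"].svs
    passed = set(svs.loc[svs["pass"], "id"])
    assert passed == set(tiny["truth"]["sv_pass"])
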