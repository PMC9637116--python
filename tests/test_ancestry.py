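"""Global ancestry assignment, local-ancestry specific variants, discordant
carriers, admixture enrichment, and the rank-sum shift test."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortscreen.ancestry import (SegmentIndex,
                                   assign_global_ancestry,
                                   component_shift_test, discordant_carriers,
                                   flag_re_mismatch, lowest_quartile_mask,
                                   admixture_enrichment)
from tests.conftest import (conditional_mle_or_oracle,
                            fisher_two_sided_oracle,
                            ranksum_two_sided_oracle)


@pytest.mark.parametrize("q, expected", [
    ((0.90, 0.07, 0.03), ("CH", 0.90)),
    ((0.20, 0.53, 0.27), ("IND", 0.53)),
    ((0.10, 0.10, 0.80), ("MY", 0.80)),
    ((1 / 3, 1 / 3, 1 / 3), ("CH", 1 / 3)),   # tie -> fixed label order
    ((0.2, 0.4, 0.4), ("IND", 0.4)),
])
def test_assign_global_ancestry(q, expected):
    anc, maxq = assign_global_ancestry(q)
    assert anc == expected[0]
    assert maxq == pytest.approx(expected[1])


def test_assign_rejects_non_simplex():
    with pytest.raises(ValueError):
        assign_global_ancestry((0.5, 0.2, 0.2))
    with pytest.raises(ValueError):
        assign_global_ancestry((0.5, 0.5))


@given(st.tuples(st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1)),
       st.permutations([0, 1, 2]))
@settings(max_examples=100, derandomize=True)
def test_assignment_equivariant_under_component_permutation(raw, perm):
    """Permuting Q components permutes the assigned label accordingly
    (up to ties)."""
    from cohortscreen.config import ANCESTRIES
    q = np.array(raw) / sum(raw)
    if len({round(v, 12) for v in q}) < 3:
        return  # ties break by label order, not equivariantly
    anc1, _ = assign_global_ancestry(q)
    q2 = q[list(perm)]
    anc2, _ = assign_global_ancestry(q2)
    assert ANCESTRIES[perm.index(ANCESTRIES.index(anc1))] == anc2


@pytest.mark.parametrize("self_rep, assigned, expected", [
    ("Chinese", "CH", False),
    ("Malay", "CH", True),
    ("IND", "IND", False),
    (None, "CH", None),
    ("Martian", "CH", None),   # unmappable: excluded
])
def test_flag_re_mismatch(self_rep, assigned, expected):
    assert flag_re_mismatch(self_rep, assigned) is expected


def test_segment_lookup_and_boundaries():
    seg = pd.DataFrame({
        "sample_id": ["s1"] * 2, "haplotype": [0, 0], "chrom": ["1"] * 2,
        "start": [1, 101], "end": [100, 200],
        "ancestry": ["CH", "MY"]})
    idx = SegmentIndex(seg)
    assert idx.lookup("s1", 0, "1", 1) == "CH"
    assert idx.lookup("s1", 0, "1", 100) == "CH"
    assert idx.lookup("s1", 0, "1", 101) == "MY"   # start coordinate decides
    assert idx.lookup("s1", 0, "1", 201) is None
    assert idx.lookup("s1", 1, "1", 50) is None
    assert idx.lookup("s2", 0, "1", 50) is None


def test_planted_specific_variants_recovered_exactly(tiny):
    """Every planted ancestry-specific variant is detected with the planted
    ancestry and allele count; allele counts honour the >=5 threshold."""
    found = {s.key: s for s in tiny["result"].specific}
    for sv in tiny["truth"]["specific_variants"]:
        if sv["allele_count"] < 5:
            continue
        assert sv["key"] in found, sv
        got = found[sv["key"]]
        assert got.ancestry == sv["ancestry"]
        assert got.allele_count == sv["allele_count"]
        assert set(got.carriers) == set(sv["carriers"])


def test_no_mixed_haplotype_variant_is_emitted(tiny):
    """Exactness: every emitted variant's carrying haplotypes map to one
    single ancestry label (re-checked directly against the segment table)."""
    bundle = tiny["bundle"]
    seg = bundle.segments
    for s in tiny["result"].specific:
        chrom, pos = s.key.split(":")[0], int(s.key.split(":")[1])
        vi = bundle.var_index(s.key)
        labels = set()
        for si in np.flatnonzero(bundle.hap[vi].any(axis=1)):
            sid = bundle.samples.index[si]
            for h in (0, 1):
                if bundle.hap[vi, si, h]:
                    hit = seg[(seg.sample_id == sid) & (seg.haplotype == h)
                              & (seg.chrom.astype(str) == chrom)
                              & (seg.start <= pos) & (seg.end >= pos)]
                    labels.add(hit.iloc[0]["ancestry"])
        assert labels == {s.ancestry}


def test_allele_count_threshold_excludes_rare(tiny):
    emitted = {s.key for s in tiny["result"].specific}
    for s in tiny["result"].specific:
        assert s.allele_count >= 5
    # planted sub-threshold variants must not appear
    for sv in tiny["truth"]["specific_variants"]:
        if sv["allele_count"] < 5:
            assert sv["key"] not in emitted


def test_planted_discordant_carriers_detected(tiny):
    det = set(zip(tiny["result"].discordant["sample_id"],
                  tiny["result"].discordant["key"]))
    for sv in tiny["truth"]["specific_variants"]:
        if sv["allele_count"] < 5:
            continue
        for sid in sv["discordant_carriers"]:
            assert (sid, sv["key"]) in det
    for _, row in tiny["result"].discordant.iterrows():
        assert row["assigned_ancestry"] != row["variant_ancestry"]


def test_discordant_with_no_specific_variants_is_empty():
    out = discordant_carriers([], pd.Series(dtype=object))
    assert len(out) == 0


def test_lowest_quartile_sizes():
    rng = np.random.default_rng(0)
    maxq = rng.uniform(0.4, 1.0, size=103)
    anc = np.array(["CH"] * 50 + ["IND"] * 29 + ["MY"] * 24, dtype=object)
    mask = lowest_quartile_mask(maxq, anc)
    for a, n in (("CH", 50), ("IND", 29), ("MY", 24)):
        got = int(mask[anc == a].sum())
        assert got == n // 4
        # the selected really are the smallest maxQ values of the group
        sel = np.sort(maxq[(anc == a) & mask])
        rest = np.sort(maxq[(anc == a) & ~mask])
        if len(sel):
            assert sel[-1] <= rest[0]


def test_quartile_requires_group_of_four():
    with pytest.raises(ValueError):
        lowest_quartile_mask(np.array([0.9, 0.8, 0.7]),
                             np.array(["CH"] * 3, dtype=object))


def test_enrichment_2x2_matches_exact_oracles():
    """Synthetic 2x2 (20 of 500 vs 5 of 1500): OR and p agree with the
    likelihood-maximisation and enumeration oracles."""
    disc = np.zeros(2000, bool)
    anc = np.array(["CH"] * 2000, dtype=object)
    maxq = np.linspace(0.5, 1.0, 2000)
    disc[:20] = True                      # lowest quartile = first 500
    disc[1500:1505] = True
    res = admixture_enrichment(disc, maxq, anc)
    cmp_ = res["comparison"]
    assert cmp_.table == ((20, 480), (5, 1495))
    assert cmp_.p_value == pytest.approx(
        fisher_two_sided_oracle(20, 500, 5, 1500), abs=1e-10)
    assert cmp_.odds_ratio == pytest.approx(
        conditional_mle_or_oracle(20, 500, 5, 1500), rel=1e-4)
    assert cmp_.ci_low <= cmp_.odds_ratio <= cmp_.ci_high


def test_enrichment_zero_cell_reports_unbounded_ci():
    disc = np.zeros(400, bool)
    anc = np.array(["CH"] * 400, dtype=object)
    maxq = np.linspace(0.5, 1.0, 400)
    disc[:10] = True                      # all discordant in lowest quartile
    res = admixture_enrichment(disc, maxq, anc)
    assert np.isinf(res["comparison"].odds_ratio)
    assert np.isinf(res["comparison"].ci_high)


def test_enrichment_with_no_discordant_is_explicit_null():
    res = admixture_enrichment(np.zeros(40, bool),
                               np.linspace(0.5, 1, 40),
                               np.array(["CH"] * 40, dtype=object))
    assert res["comparison"] is None


def test_enrichment_present_in_synthetic_cohort(tiny):
    """Planted discordant carriers are admixed, so discordance concentrates
    in the lowest maxQ quartile."""
    cmp_ = tiny["result"].enrichment["comparison"]
    assert cmp_ is not None
    assert cmp_.odds_ratio > 1.0


# ---- Wilcoxon rank-sum ----------------------------------------------------

def test_ranksum_identical_groups_p_one():
    _, p = component_shift_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0)


def test_ranksum_matches_exhaustive_enumeration():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    _, p = component_shift_test(x, y)
    assert p == pytest.approx(ranksum_two_sided_oracle(x, y), abs=1e-10)
    x, y = [1.0, 4.0, 7.0, 9.0], [2.0, 3.0, 5.0]
    _, p = component_shift_test(x, y)
    assert p == pytest.approx(ranksum_two_sided_oracle(x, y), abs=1e-10)


def test_ranksum_type_i_error_calibrated():
    """Under the null (no shift), rejection rate at alpha = 0.05 stays
    within Monte-Carlo error over 10,000 replicates."""
    rng = np.random.default_rng(5)
    alpha, reps = 0.05, 10_000
    rejections = 0
    for _ in range(reps):
        x = rng.normal(size=20)
        y = rng.normal(size=25)
        _, p = component_shift_test(x, y)
        rejections += p < alpha
    rate = rejections / reps
    assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)


def test_ranksum_empty_group_is_error():
    with pytest.raises(ValueError):
        component_shift_test([], [1.0])


def test_carriers_shifted_component_detected(tiny):
    """Carriers of an ancestry-specific variant carry more of that
    ancestral component than non-carriers of other assigned ancestries."""
    r, bundle = tiny["result"], tiny["bundle"]
    from cohortscreen.config import ANCESTRIES
    for sv in r.specific:
        if not len(r.discordant[r.discordant["key"] == sv.key]):
            continue
        j = ANCESTRIES.index(sv.ancestry)
        other = r.assigned != sv.ancestry
        is_carrier = bundle.samples.index.isin(sv.carriers)
        comp = bundle.Q[:, j]
        x = comp[other & is_carrier]
        y = comp[other & ~is_carrier]
        if len(x) >= 2:
            assert np.median(x) > np.median(y)
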