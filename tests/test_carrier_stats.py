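"""Carrier frequencies, prevalence, Fisher exact comparisons and BH
correction, cross-checked against enumeration oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortscreen.carrier_stats import (adjusted_carrier_frequency, bh_adjust,
                                        cohort_prevalence,
                                        compare_across_ancestries,
                                        fisher_group_comparison,
                                        variant_carrier_table)
from tests.conftest import conditional_mle_or_oracle, fisher_two_sided_oracle


def flags(k, n):
    f = np.zeros(n, bool)
    f[:k] = True
    return f


@pytest.mark.parametrize("k, n, expected", [
    (1094, 5502, 19.88),   # GJB2 among Chinese
    (325, 1941, 16.74),    # HFE among Indians
    (0, 100, 0.0),
])
def test_adjusted_carrier_frequency_printed_examples(k, n, expected):
    cell = adjusted_carrier_frequency(flags(k, n))
    assert cell == {"carriers": k, "n": n, "carrier_freq_pct": expected}


@pytest.mark.parametrize("k, n, expected", [
    (238, 9051, 2.63),
    (309, 9051, 3.41),
    (0, 50, 0.0),
])
def test_cohort_prevalence(k, n, expected):
    assert cohort_prevalence(flags(k, n)) == expected


def test_prevalence_rounding_is_half_up():
    # 23/1000 = 2.3 %, 225/10000 = 2.25 % -> 2.25; half-up case: 5/160
    assert cohort_prevalence(flags(5, 160)) == 3.13  # 3.125 rounds up


def test_carrier_counts_sum_over_ancestry_groups(tiny):
    """Disjoint ancestry groups partition the cohort carrier count."""
    r = tiny["result"]
    total = r.gene_table.groupby("gene")["carriers"].sum()
    from cohortscreen.carrier_stats import carrier_matrix
    mat = carrier_matrix(tiny["bundle"], r.classes)
    for gene in mat.columns:
        assert total[gene] == int(mat[gene].sum())


def test_gene_carrier_truth_recovered_exactly(tiny):
    """End-to-end: per-gene per-ancestry carrier counts equal the
    generator's post-QC planted truth for every gene."""
    gt = tiny["result"].gene_table.set_index(["gene", "ancestry"])
    for gene, by_anc in tiny["truth"]["carrier_truth"].items():
        for anc, expected in by_anc.items():
            assert int(gt.loc[(gene, anc), "carriers"]) == expected, \
                (gene, anc)


def test_hemizygous_males_counted_once(tiny):
    """G6PD is X-linked: male hemizygotes (written as hom-alt) are carriers,
    counted once each."""
    bundle, r = tiny["bundle"], tiny["result"]
    from cohortscreen.carrier_stats import gene_carrier_flags
    g6pd = gene_carrier_flags(bundle, r.classes, "G6PD")
    male = (bundle.samples["sex"] == "M").to_numpy()
    assert (g6pd & male).sum() > 0
    assert int(g6pd.sum()) == sum(tiny["truth"]["carrier_truth"]
                                  ["G6PD"].values())


def test_in_cis_pair_counted_as_one_event(tiny):
    bundle, r = tiny["bundle"], tiny["result"]
    (k1, k2), = bundle.in_cis
    table = variant_carrier_table(bundle, r.classes, r.assigned)
    events = set(table["event"])
    assert f"{k1}+{k2}" in events
    assert k1 not in events and k2 not in events
    merged = table[table["event"] == f"{k1}+{k2}"]["carriers"].sum()
    union = ((bundle.dosage[bundle.var_index(k1)] > 0)
             | (bundle.dosage[bundle.var_index(k2)] > 0)).sum()
    assert merged == union


# ---- Fisher exact ---------------------------------------------------------

def test_fisher_identical_proportions_p_one():
    cmp_ = fisher_group_comparison(10, 100, 10, 100)
    assert cmp_.p_value == pytest.approx(1.0)
    assert cmp_.ci_low <= cmp_.odds_ratio <= cmp_.ci_high


@pytest.mark.parametrize("k1, n1, k2, n2", [
    (3, 100, 0, 100),
    (58, 5502, 3, 1941),
    (5, 20, 1, 25),
    (0, 10, 0, 12),
])
def test_fisher_p_matches_hypergeometric_enumeration(k1, n1, k2, n2):
    cmp_ = fisher_group_comparison(k1, n1, k2, n2)
    assert cmp_.p_value == pytest.approx(
        fisher_two_sided_oracle(k1, n1, k2, n2), abs=1e-10)


@pytest.mark.parametrize("k1, n1, k2, n2", [
    (58, 5502, 3, 1941),
    (20, 500, 5, 1500),
    (5, 20, 1, 25),
])
def test_conditional_mle_odds_ratio_matches_likelihood_maximum(k1, n1,
                                                               k2, n2):
    cmp_ = fisher_group_comparison(k1, n1, k2, n2)
    oracle = conditional_mle_or_oracle(k1, n1, k2, n2)
    assert cmp_.odds_ratio == pytest.approx(oracle, rel=1e-4)


def test_fisher_zero_cell_gives_unbounded_ci():
    cmp_ = fisher_group_comparison(5, 20, 0, 100)
    assert np.isinf(cmp_.odds_ratio) or cmp_.ci_high == np.inf


def test_fisher_empty_group_is_error():
    with pytest.raises(ValueError):
        fisher_group_comparison(0, 0, 1, 10)


# ---- Benjamini-Hochberg ---------------------------------------------------

def test_bh_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)


def test_bh_preserves_input_order():
    p = [0.04, 0.01, 0.03, 0.02]
    adj = bh_adjust(p)
    assert list(adj) == pytest.approx([0.04] * 4)
    p = [0.5, 0.001, 0.9]
    adj = bh_adjust(p)
    assert adj[1] == min(adj)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
@settings(max_examples=150, derandomize=True)
def test_bh_monotone_and_dominating(p):
    adj = bh_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)        # adjusted >= raw
    assert np.all((adj >= 0) & (adj <= 1))
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)       # monotone in rank


@pytest.mark.parametrize("p", [
    [0.03],                       # m = 1
    [0.2, 0.2, 0.2, 0.2],         # tied inputs are fixed points
    [1.0, 1.0],
    [0.0, 0.0, 0.5],
])
def test_bh_idempotent_on_fixed_point_inputs(p):
    """Step-up adjustment is a fixed point on tied/degenerate inputs.

    (It is not idempotent on arbitrary adjusted vectors: for p = [0, 0.5, 1]
    the adjusted vector [0, 0.75, 1] re-adjusts to [0, 1, 1] because the
    rank weight m/i re-inflates interior values — a property of the
    procedure itself, demonstrated here.)"""
    adj = bh_adjust(p)
    assert bh_adjust(adj) == pytest.approx(list(adj))
    again = bh_adjust(bh_adjust([0.0, 0.5, 1.0]))
    assert list(again) == pytest.approx([0.0, 1.0, 1.0])


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


def test_compare_across_ancestries_emits_bh_family(tiny):
    r = tiny["result"]
    out = compare_across_ancestries(r.gene_table, "CH", "IND")
    assert len(out) == r.gene_table["gene"].nunique()
    assert (out["p_bh"] >= out["p"] - 1e-15).all()
    assert out["bh_family"].nunique() == 1


def test_age_restricted_view_uses_filtered_denominator(tiny):
    from cohortscreen.carrier_stats import carrier_table
    bundle, r = tiny["bundle"], tiny["result"]
    young = (bundle.samples["age"] <= 50).to_numpy()
    t = carrier_table(bundle, r.classes, r.assigned, sample_mask=young)
    for anc in ("CH", "IND", "MY"):
        n = t[t["ancestry"] == anc]["n"].iloc[0]
        assert n == int(((r.assigned == anc) & young).sum())
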