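"""Shared fixtures: generated synthetic bundles at two scales plus
independent statistical oracles used across test modules."""

from __future__ import annotations

from math import comb

import numpy as np
import pytest

from cohortscreen import generate_cohort, load_bundle, run_pipeline
from cohortscreen.config import PlantedSpecificVariant, SimConfig

TINY_N = {"CH": 300, "IND": 110, "MY": 90}
# study proportions at n = 2000 for parameter-recovery checks; the planted
# ancestry-specific variants are scaled down with the cohort so they do not
# distort gene-level carrier frequencies
RECOVERY_N = {"CH": 1216, "IND": 428, "MY": 356}
RECOVERY_SPECIFIC = (
    PlantedSpecificVariant("NOTCH3", "CH", allele_count=6, n_discordant=1),
    PlantedSpecificVariant("GNE", "IND", allele_count=6, n_discordant=1),
    PlantedSpecificVariant("HBB", "MY", allele_count=6, n_discordant=1),
)


@pytest.fixture(scope="session")
def tiny(tmp_path_factory):
    """Small cohort exercising every pipeline branch quickly."""
    out = tmp_path_factory.mktemp("tiny_bundle")
    cfg = SimConfig(seed=7, n_per_ancestry=dict(TINY_N))
    truth = generate_cohort(cfg, out)
    bundle = load_bundle(out)
    result = run_pipeline(bundle)
    return {"dir": out, "cfg": cfg, "truth": truth, "bundle": bundle,
            "result": result}


@pytest.fixture(scope="session")
def recovery(tmp_path_factory):
    """n = 2000 cohort at study proportions for truth-recovery checks."""
    out = tmp_path_factory.mktemp("recovery_bundle")
    cfg = SimConfig(seed=11, n_per_ancestry=dict(RECOVERY_N),
                    planted_specific_variants=RECOVERY_SPECIFIC)
    truth = generate_cohort(cfg, out)
    bundle = load_bundle(out)
    result = run_pipeline(bundle)
    return {"dir": out, "cfg": cfg, "truth": truth, "bundle": bundle,
            "result": result}


# --------------------------------------------------------------------------
# independent oracles


def fisher_two_sided_oracle(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration over all
    tables with the observed margins."""
    N, K = n1 + n2, k1 + k2

    def prob(x):
        return comb(n1, x) * comb(n2, K - x) / comb(N, K)

    p_obs = prob(k1)
    lo, hi = max(0, K - n2), min(K, n1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def conditional_mle_or_oracle(k1: int, n1: int, k2: int, n2: int) -> float:
    """Conditional-MLE odds ratio by directly maximising the Fisher
    noncentral hypergeometric likelihood over log-odds (golden search)."""
    from scipy.stats import nchypergeom_fisher
    N, K = n1 + n2, k1 + k2
    lo, hi = max(0, K - n2), min(K, n1)
    if k1 == lo:
        return 0.0
    if k1 == hi:
        return np.inf

    def nll(logpsi):
        return -nchypergeom_fisher.logpmf(k1, N, n1, K, np.exp(logpsi))

    from scipy.optimize import minimize_scalar
    res = minimize_scalar(nll, bounds=(-20, 20), method="bounded",
                          options={"xatol": 1e-10})
    return float(np.exp(res.x))


def ranksum_two_sided_oracle(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating every assignment of pooled
    ranks to the first group (tie-free samples only)."""
    from itertools import combinations
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    m, n = len(x), len(y)
    sums = [sum(c) for c in combinations(range(1, m + n + 1), m)]
    total = len(sums)
    p_low = sum(s <= w_obs for s in sums) / total
    p_high = sum(s >= w_obs for s in sums) / total
    return min(1.0, 2 * min(p_low, p_high))


def hotspot_oracle(plp, blb, window=25, min_plp=3):
    """Exhaustive per-start window scan (the reference for the fast
    hotspot detector)."""
    plp, blb = sorted(plp), sorted(blb)
    if not plp:
        return []
    out = []
    for s in range(min(plp) - window + 1, max(plp) + 1):
        e = s + window - 1
        n_p = sum(s <= p <= e for p in plp)
        n_b = sum(s <= b <= e for b in blb)
        if n_p >= min_plp and n_b < n_p:
            out.append((s, e))
    return out


def binom_interval(n: int, p: float, conf: float = 0.99) -> tuple[int, int]:
    from scipy.stats import binom
    lo, hi = binom.interval(conf, n, p)
    return int(lo), int(hi)
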