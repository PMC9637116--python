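"""Global and local ancestry analyses.

Global ancestry is the argmax of the K=3 ADMIXTURE Q vector (fixed label
order CH, IND, MY for ties), with maxQ — the largest component — serving as
an inverse measure of admixture. Ancestry-specific variants are P/LP
variants with allele count >= 5 whose every carrying haplotype sits on a
local-ancestry segment of one single ancestry; discordant carriers are
individuals whose assigned global ancestry differs from a carried variant's
specific ancestry. Enrichment of discordance among admixed individuals is
tested on the pooled 2x2 of discordant-carrier status against
lowest-within-ancestry-quartile maxQ membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .carrier_stats import fisher_group_comparison
from .config import ANCESTRIES
from .ingest import CohortBundle

log = logging.getLogger(__name__)

#: Editable free-text mapping from self-reported race/ethnicity labels to
#: the three genetic ancestry groups.
RE_LABEL_MAP: dict[str, str] = {
    "CH": "CH", "IND": "IND", "MY": "MY",
    "Chinese": "CH", "Indian": "IND", "Malay": "MY",
}


def assign_global_ancestry(q, tol: float = 1e-6) -> tuple[str, float]:
    """(ancestry, maxQ) from a K=3 simplex vector; ties break in fixed
    label order CH, IND, MY."""
    q = np.asarray(q, dtype=float)
    if q.shape != (3,):
        raise ValueError("Q vector must have length 3")
    if abs(q.sum() - 1.0) > tol:
        raise ValueError(f"Q vector sums to {q.sum()}, not 1")
    i = int(np.argmax(q))  # np.argmax takes the first max -> fixed order
    return ANCESTRIES[i], float(q[i])


def assign_all(Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised assignment over a Q matrix; returns (labels, maxQ)."""
    Q = np.asarray(Q, dtype=float)
    if np.any(np.abs(Q.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("Q rows must sum to 1")
    idx = Q.argmax(axis=1)
    return np.array(ANCESTRIES, dtype=object)[idx], Q.max(axis=1)


def flag_re_mismatch(self_reported: str | None, assigned: str,
                     label_map: dict[str, str] = RE_LABEL_MAP) -> bool | None:
    """True iff the mapped self-reported label differs from the assigned
    genetic ancestry; None when missing or unmappable (excluded)."""
    if self_reported is None or (isinstance(self_reported, float)
                                 and np.isnan(self_reported)):
        return None
    mapped = label_map.get(str(self_reported))
    if mapped is None:
        log.warning("unmappable self-reported label %r", self_reported)
        return None
    return mapped != assigned


class SegmentIndex:
    """Per-(sample, haplotype, chromosome) interval lookup over an
    RFMix-msp-style segment table (1-based inclusive coordinates)."""

    def __init__(self, segments: pd.DataFrame):
        self._idx: dict[tuple[str, int, str], tuple[np.ndarray, np.ndarray,
                                                    list[str]]] = {}
        for (sid, hap, chrom), sub in segments.groupby(
                ["sample_id", "haplotype", "chrom"], sort=False):
            sub = sub.sort_values("start")
            self._idx[(sid, int(hap), str(chrom))] = (
                sub["start"].to_numpy(), sub["end"].to_numpy(),
                list(sub["ancestry"]))

    def lookup(self, sample_id: str, hap: int, chrom: str,
               pos: int) -> str | None:
        """Ancestry label of the segment containing the position (the
        segment containing the start coordinate decides boundary cases)."""
        entry = self._idx.get((sample_id, int(hap), str(chrom)))
        if entry is None:
            return None
        starts, ends, labels = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos > ends[i]:
            return None
        return labels[i]


@dataclass(frozen=True)
class AncestrySpecificVariant:
    key: str
    gene: str
    ancestry: str
    allele_count: int
    carriers: tuple[str, ...]


def ancestry_specific_variants(bundle: CohortBundle, classes: pd.DataFrame,
                               seg_index: SegmentIndex | None = None,
                               min_ac: int = 5
                               ) -> list[AncestrySpecificVariant]:
    """P/LP variants whose carrying haplotypes are all labelled with one
    single local ancestry and whose allele count reaches ``min_ac``."""
    seg_index = seg_index or SegmentIndex(bundle.segments)
    sample_ids = list(bundle.samples.index)
    out = []
    plp_keys = classes.index[classes["category"] == "P/LP"]
    for key in plp_keys:
        row = bundle.variants.loc[key]
        vi = bundle.var_index(key)
        hap = bundle.hap[vi]
        carriers = np.flatnonzero(hap.any(axis=1))
        ac = int(hap.sum())
        if ac < min_ac:
            continue
        labels = set()
        covered = True
        for s in carriers:
            for h in (0, 1):
                if hap[s, h]:
                    lab = seg_index.lookup(sample_ids[s], h,
                                           str(row["chrom"]),
                                           int(row["pos"]))
                    if lab is None:
                        covered = False
                        break
                    labels.add(lab)
            if not covered or len(labels) > 1:
                break
        if not covered:
            log.warning("carrier haplotype of %s not covered by any "
                        "segment: variant skipped", key)
            continue
        if len(labels) == 1:
            out.append(AncestrySpecificVariant(
                key, row["gene"], labels.pop(), ac,
                tuple(sample_ids[s] for s in carriers)))
    return out


def discordant_carriers(specific: list[AncestrySpecificVariant],
                        assigned: pd.Series,
                        re_match: pd.Series | None = None) -> pd.DataFrame:
    """Carriers whose assigned global ancestry differs from the carried
    variant's specific ancestry, annotated with R/E-match status."""
    rows = []
    for var in specific:
        for sid in var.carriers:
            if assigned.loc[sid] != var.ancestry:
                rows.append({
                    "sample_id": sid, "key": var.key, "gene": var.gene,
                    "variant_ancestry": var.ancestry,
                    "assigned_ancestry": assigned.loc[sid],
                    "re_matched": (bool(re_match.loc[sid])
                                   if re_match is not None else None)})
    cols = ["sample_id", "key", "gene", "variant_ancestry",
            "assigned_ancestry", "re_matched"]
    return pd.DataFrame(rows, columns=cols)


def lowest_quartile_mask(maxq: np.ndarray, assigned: np.ndarray
                         ) -> np.ndarray:
    """Within-ancestry lowest-maxQ quartile membership (k = floor(n/4) per
    group, stable rank order breaking ties); pooled across groups."""
    maxq = np.asarray(maxq, float)
    assigned = np.asarray(assigned, object)
    mask = np.zeros(maxq.size, bool)
    for anc in sorted(set(assigned)):
        idx = np.flatnonzero(assigned == anc)
        if idx.size < 4:
            raise ValueError(f"group {anc} too small for quartiles")
        k = idx.size // 4
        order = idx[np.argsort(maxq[idx], kind="stable")]
        mask[order[:k]] = True
    return mask


def admixture_enrichment(discordant_flag: np.ndarray, maxq: np.ndarray,
                         assigned: np.ndarray) -> dict:
    """Association of discordant-carrier status with high admixture
    (lowest within-ancestry maxQ quartile), pooled Fisher 2x2 plus a
    per-ancestry breakdown."""
    disc = np.asarray(discordant_flag, bool)
    low = lowest_quartile_mask(maxq, assigned)
    if disc.sum() == 0:
        return {"comparison": None, "note": "no discordant carriers",
                "per_ancestry": {}}
    k1, n1 = int((disc & low).sum()), int(low.sum())
    k2, n2 = int((disc & ~low).sum()), int((~low).sum())
    cmp_ = fisher_group_comparison(k1, n1, k2, n2,
                                   label="discordant_x_lowest_quartile")
    per_anc = {}
    for anc in sorted(set(np.asarray(assigned, object))):
        g = np.asarray(assigned, object) == anc
        per_anc[anc] = {
            "discordant_low_quartile": int((disc & low & g).sum()),
            "discordant_other": int((disc & ~low & g).sum()),
            "n_low_quartile": int((low & g).sum()),
            "n_other": int((~low & g).sum())}
    return {"comparison": cmp_, "per_ancestry": per_anc}


def component_shift_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test for a shift in an ancestral
    component between carriers and non-carriers: exact null distribution
    for small tie-free samples, normal approximation with tie correction
    otherwise. Returns (U statistic, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
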