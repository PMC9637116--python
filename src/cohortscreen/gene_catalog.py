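"""Gene-catalog semantics: loss-of-function intolerance and the
carrier-screening panel gap analysis."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .utils import pct


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    inheritance: str
    clingen_hi: bool = False
    pli: float | None = None
    twoplus_plp_lof_count: int = 0
    severe: bool = False
    panels: tuple[str, ...] = ()


def is_lofi(gene: GeneRecord | pd.Series) -> tuple[bool, set[str]]:
    """A gene is loss-of-function intolerant if any criterion holds:
    (1) ClinGen haploinsufficient, (2) >=3 ClinVar TwoPlus P/LP LOF variants
    (frameshift / nonsense / essential splice), (3) pLI strictly > 0.9.
    Returns the verdict and the set of criteria satisfied."""
    if isinstance(gene, pd.Series):
        pli = gene.get("pli")
        pli = None if pli in ("", None) or pd.isna(pli) else float(pli)
        gene = GeneRecord(
            symbol=str(gene.name), inheritance=gene.get("inheritance", ""),
            clingen_hi=bool(gene.get("clingen_hi", 0)),
            pli=pli,
            twoplus_plp_lof_count=int(gene.get("twoplus_plp_lof_count", 0)))
    fired = set()
    if gene.clingen_hi:
        fired.add("clingen_hi")
    if gene.twoplus_plp_lof_count >= 3:
        fired.add("clinvar_lof")
    if gene.pli is not None and gene.pli > 0.9:
        fired.add("pli")
    return bool(fired), fired


def lofi_genes(catalog: pd.DataFrame) -> set[str]:
    """Symbols of all LOFi genes in a catalog table (index = gene)."""
    return {g for g, row in catalog.iterrows() if is_lofi(row)[0]}


def panel_gap_analysis(max_carrier_freq: "pd.Series[float]",
                       catalog: pd.DataFrame,
                       threshold: float = 0.005) -> dict:
    """Partition recessive genes whose maximum per-ancestry carrier
    frequency exceeds ``threshold`` (strict, as a fraction) into ACMG
    carrier-screening, commercial-panel-only, and uncovered sets, and report
    the severe-recessive subset with its uncovered fraction.

    ``max_carrier_freq``: gene -> max carrier frequency across ancestries
    (fractions in [0, 1])."""
    rec = catalog[catalog["inheritance"].isin(["AR", "XL"])]
    qualifying = [g for g in rec.index
                  if float(max_carrier_freq.get(g, 0.0)) > threshold]
    acmg, commercial, uncovered = [], [], []
    for g in qualifying:
        panels = str(rec.loc[g, "panels"] or "")
        panels = set(p for p in panels.split(",") if p)
        if "acmg_carrier" in panels:
            acmg.append(g)
        elif "commercial_carrier" in panels:
            commercial.append(g)
        else:
            uncovered.append(g)
    severe = [g for g in qualifying if bool(rec.loc[g, "severe"])]
    severe_uncovered = [g for g in severe if g in set(uncovered)]
    return {
        "threshold": threshold,
        "qualifying": qualifying,
        "acmg_carrier": acmg,
        "commercial_only": commercial,
        "uncovered": uncovered,
        "severe": severe,
        "severe_uncovered": severe_uncovered,
        "severe_uncovered_pct": (
            pct(len(severe_uncovered), len(severe), 0) if severe else 0.0),
    }
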