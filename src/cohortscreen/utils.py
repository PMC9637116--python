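"""Small shared helpers: reporting-grade rounding and variant keys."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero to ``ndigits`` decimal places.

    Reported percentages follow table-style rounding (22.95 -> 23.0), not
    banker's rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage of ``count`` out of ``total``, rounded half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, ndigits)


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical string key for a biallelic site+allele."""
    return f"{chrom}:{pos}:{ref}:{alt}"


def parse_variant_key(key: str) -> tuple[str, int, str, str]:
    chrom, pos, ref, alt = key.split(":")
    return chrom, int(pos), ref, alt
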