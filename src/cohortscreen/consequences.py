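"""Fixed, severity-ordered consequence vocabulary (Ensembl/VEP ranking).

The order is the standard Ensembl consequence-severity table (most severe
first). ``severity_rank`` gives a smaller number for a more severe term, so
sorting by rank picks the most deleterious consequence deterministically.
"""

from __future__ import annotations

SEVERITY_ORDER: tuple[str, ...] = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_region_variant",
    "splice_donor_5th_base_variant",
    "incomplete_terminal_codon_variant",
    "start_retained_variant",
    "stop_retained_variant",
    "synonymous_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "NMD_transcript_variant",
    "non_coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
)

_RANK = {term: i for i, term in enumerate(SEVERITY_ORDER)}

#: Loss-of-function consequences: frameshift indels, nonsense, and essential
#: splice-site (+/-2) variants.
LOF_CONSEQUENCES: frozenset[str] = frozenset(
    {
        "frameshift_variant",
        "stop_gained",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)

#: Consequences that are at least protein-altering; used to decide whether an
#: unassessable variant is a VUS (interpretable) or falls through Unclassified.
PROTEIN_ALTERING_MIN_RANK = _RANK["splice_region_variant"]


def severity_rank(term: str) -> int:
    """Rank of a consequence term; unknown terms raise ``KeyError``."""
    return _RANK[term]


def is_lof(term: str) -> bool:
    return term in LOF_CONSEQUENCES


def known_term(term: str) -> bool:
    return term in _RANK
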