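"""Simulation configuration: the planted ground truth of the synthetic cohort.

The default configuration mirrors the published study conditions: a
three-ancestry cohort (Chinese, Indian, Malay; 5502/1941/1608 individuals),
gene-level carrier frequencies taken from the study's top-burden tables, a
small severe-recessive panel driving the at-risk-couple estimate, ClinVar-style
evidence including classification edge cases, ancestry-specific variants laid
onto local-ancestry tracks, and pharmacogene allele frequencies echoing the
published actionable-phenotype table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

ANCESTRIES: tuple[str, ...] = ("CH", "IND", "MY")


class ConfigError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


@dataclass(frozen=True)
class PlantedGene:
    """A gene with one recurrent planted variant at per-ancestry carrier frequency.

    ``excluded`` marks the planted variant as a member of the at-risk-couple
    exclusion list (clinically significant only in trans with a more severe
    allele), e.g. mild GJB2 p.Val37Ile-like or BTD p.Asp424His-like alleles.
    """

    gene: str
    inheritance: str  # AD | AR | XL
    carrier_freq: dict[str, float]
    severe: bool = False
    excluded: bool = False
    panels: tuple[str, ...] = ()
    domain: str = "other"
    condition: str = ""  # CDC Tier 1 condition tag: HBOC | Lynch | FH | ""
    variant_type: str = "missense_variant"
    # LOFi evidence carried in the gene catalog
    clingen_hi: bool = False
    pli: float | None = None
    twoplus_plp_lof_count: int = 0
    strand: str = "+"


@dataclass(frozen=True)
class PlantedSpecificVariant:
    """An ancestry-specific P/LP variant carried only on matching local-ancestry
    haplotype segments; ``n_discordant`` carriers are planted in individuals
    whose global ancestry differs from the variant's ancestry."""

    gene: str
    ancestry: str
    allele_count: int
    n_discordant: int = 1


@dataclass(frozen=True)
class PlantedHotspot:
    """A 25-bp window seeded with TwoPlus P/LP anchors (and optionally B/LB
    decoys); when ``resident_revel`` is given, a missense VUS with that REVEL
    score is planted inside the window."""

    gene: str
    n_plp: int = 3
    n_benign: int = 0
    spacing: int = 10
    resident_revel: float | None = 0.85


@dataclass(frozen=True)
class PgxAllele:
    name: str
    function: str  # increased | normal | decreased | none
    freq: dict[str, float]


def _f(ch: float, ind: float, my: float) -> dict[str, float]:
    return {"CH": ch, "IND": ind, "MY": my}


# Gene roster: carrier frequencies follow the study's per-ancestry burden
# tables; LOFi evidence fields and panel memberships are synthetic stand-ins.
DEFAULT_GENES: tuple[PlantedGene, ...] = (
    # --- dominant disorder genes ---
    PlantedGene("NOTCH3", "AD", _f(0.0091, 0.0005, 0.0), domain="Neuro",
                clingen_hi=False, pli=0.0, twoplus_plp_lof_count=1),
    PlantedGene("PRSS1", "AD", _f(0.0211, 0.0005, 0.0087), domain="Gastro-HPB"),
    PlantedGene("LDLR", "AD", _f(0.0076, 0.0010, 0.0012), domain="Lipid",
                panels=("acmg_sf_v2", "acmg_sf_v3"), condition="FH",
                clingen_hi=True, pli=0.96, twoplus_plp_lof_count=6),
    PlantedGene("APOB", "AD", _f(0.0033, 0.0021, 0.0025), domain="Lipid",
                panels=("acmg_sf_v2", "acmg_sf_v3"), condition="FH"),
    PlantedGene("BRCA1", "AD", _f(0.0015, 0.0031, 0.0031), domain="Cancer",
                panels=("acmg_sf_v2", "acmg_sf_v3"), condition="HBOC",
                clingen_hi=True, pli=0.0, twoplus_plp_lof_count=7),
    PlantedGene("BRCA2", "AD", _f(0.0035, 0.0036, 0.0037), domain="Cancer",
                panels=("acmg_sf_v2", "acmg_sf_v3"), condition="HBOC",
                pli=0.0, twoplus_plp_lof_count=9),
    PlantedGene("PALB2", "AD", _f(0.0015, 0.0, 0.0019), domain="Cancer",
                panels=("acmg_sf_v3",), twoplus_plp_lof_count=5),
    PlantedGene("MSH6", "AD", _f(0.0013, 0.0, 0.0006), domain="Cancer",
                panels=("acmg_sf_v2", "acmg_sf_v3"), condition="Lynch",
                twoplus_plp_lof_count=4),
    PlantedGene("MLH1", "AD", _f(0.0008, 0.0005, 0.0006), domain="Cancer",
                panels=("acmg_sf_v2", "acmg_sf_v3"), condition="Lynch",
                clingen_hi=True, pli=0.88, twoplus_plp_lof_count=6),
    PlantedGene("TTN", "AD", _f(0.0060, 0.0067, 0.0044), domain="CVD",
                panels=("acmg_sf_v3",), pli=0.0),
    PlantedGene("MYBPC3", "AD", _f(0.0005, 0.0041, 0.0006), domain="CVD",
                panels=("acmg_sf_v2", "acmg_sf_v3"), twoplus_plp_lof_count=6),
    PlantedGene("KCNQ1", "AD", _f(0.0007, 0.0015, 0.0012), domain="CVD",
                panels=("acmg_sf_v2", "acmg_sf_v3"), pli=0.97),
    # --- recessive disorder genes (severe set drives the ARC estimate) ---
    PlantedGene("GJB2", "AR", _f(0.1988, 0.0361, 0.1592), severe=True,
                excluded=True, panels=("acmg_carrier", "commercial_carrier"),
                domain="Others"),
    PlantedGene("CFTR", "AR", _f(0.0832, 0.0350, 0.1642), severe=True,
                excluded=True, panels=("acmg_carrier", "commercial_carrier"),
                domain="Respiratory", twoplus_plp_lof_count=8),
    PlantedGene("HBB", "AR", _f(0.0171, 0.0118, 0.0765), severe=True,
                panels=("acmg_carrier", "commercial_carrier"),
                domain="Haem/Immuno", twoplus_plp_lof_count=5),
    PlantedGene("SLC25A13", "AR", _f(0.0229, 0.0010, 0.0), severe=True,
                panels=("commercial_carrier",), domain="Metab.",
                variant_type="frameshift_variant", twoplus_plp_lof_count=4),
    PlantedGene("GNE", "AR", _f(0.0035, 0.0340, 0.0081), severe=True,
                domain="Neuro"),
    PlantedGene("MYO15A", "AR", _f(0.0073, 0.0283, 0.0106), severe=True,
                panels=("commercial_carrier",), domain="Others"),
    PlantedGene("ABCA4", "AR", _f(0.0095, 0.0309, 0.0429), severe=True,
                domain="Ocular"),
    PlantedGene("SLC26A4", "AR", _f(0.0198, 0.0067, 0.0106), severe=True,
                panels=("commercial_carrier",), domain="Others"),
    PlantedGene("DUOX2", "AR", _f(0.0324, 0.0134, 0.0236), severe=True,
                domain="Metab."),
    PlantedGene("SLC22A5", "AR", _f(0.0140, 0.0222, 0.0031), severe=True,
                panels=("commercial_carrier",), domain="Metab."),
    PlantedGene("POLG", "AR", _f(0.0211, 0.0026, 0.0330), severe=True,
                panels=("commercial_carrier",), domain="Neuro", strand="-"),
    PlantedGene("GAA", "AR", _f(0.0120, 0.0050, 0.0040), severe=True,
                panels=("acmg_carrier", "commercial_carrier"), domain="Metab."),
    PlantedGene("ARHGEF18", "AR", _f(0.0029, 0.0031, 0.0193), severe=True,
                domain="Ocular"),
    PlantedGene("BTD", "AR", _f(0.0027, 0.0742, 0.0044), severe=True,
                excluded=True, panels=("commercial_carrier",), domain="Metab."),
    PlantedGene("HFE", "AR", _f(0.0563, 0.1674, 0.0491),
                panels=("commercial_carrier",), domain="Metab."),
    PlantedGene("CD36", "AR", _f(0.0596, 0.0005, 0.0025), domain="Haem/Immuno"),
    PlantedGene("IL36RN", "AR", _f(0.0347, 0.0010, 0.0062), domain="Derm"),
    PlantedGene("SERPINB7", "AR", _f(0.0198, 0.0005, 0.0019), domain="Derm"),
    PlantedGene("SPINK1", "AR", _f(0.0151, 0.0438, 0.0622), domain="Gastro-HPB"),
    PlantedGene("F5", "AR", _f(0.0013, 0.0252, 0.0050),
                panels=("commercial_carrier",), domain="Haem/Immuno"),
    # --- X-linked ---
    PlantedGene("G6PD", "XL", _f(0.0294, 0.0165, 0.0286),
                panels=("commercial_carrier",), domain="Metab."),
)

DEFAULT_SPECIFIC_VARIANTS: tuple[PlantedSpecificVariant, ...] = (
    PlantedSpecificVariant("NOTCH3", "CH", allele_count=12, n_discordant=2),
    PlantedSpecificVariant("SLC25A13", "CH", allele_count=8, n_discordant=1),
    PlantedSpecificVariant("GNE", "IND", allele_count=10, n_discordant=1),
    PlantedSpecificVariant("MYO15A", "IND", allele_count=9, n_discordant=1),
    PlantedSpecificVariant("HBB", "MY", allele_count=14, n_discordant=2),
    PlantedSpecificVariant("ARHGEF18", "MY", allele_count=7, n_discordant=1),
)

DEFAULT_HOTSPOTS: tuple[PlantedHotspot, ...] = (
    PlantedHotspot("LDLR", n_plp=3, n_benign=0, resident_revel=0.85),
    PlantedHotspot("KCNQ1", n_plp=3, n_benign=1, resident_revel=0.88),
    # benign-majority decoy window: does not qualify, resident stays VUS
    PlantedHotspot("MYBPC3", n_plp=3, n_benign=3, resident_revel=0.90),
)

# Pharmacogene allele-frequency tables (allele frequencies, summing to 1 per
# ancestry with the listed reference allele). Functions feed the phenotype
# rule table shipped under data/pgx_phenotype_rules.tsv.
DEFAULT_PGX: dict[str, tuple[PgxAllele, ...]] = {
    "CYP2B6": (
        PgxAllele("*1", "normal", _f(0.775, 0.597, 0.558)),
        PgxAllele("*4", "increased", _f(0.005, 0.003, 0.002)),
        PgxAllele("*6", "decreased", _f(0.20, 0.35, 0.40)),
        PgxAllele("*18", "none", _f(0.02, 0.05, 0.04)),
    ),
    "CYP2C9": (
        PgxAllele("*1", "normal", _f(0.964, 0.84, 0.97)),
        PgxAllele("*2", "decreased", _f(0.001, 0.05, 0.005)),
        PgxAllele("*3", "none", _f(0.035, 0.11, 0.025)),
    ),
    "CYP2C19": (
        PgxAllele("*1", "normal", _f(0.645, 0.51, 0.73)),
        PgxAllele("*2", "none", _f(0.28, 0.30, 0.22)),
        PgxAllele("*3", "none", _f(0.06, 0.01, 0.02)),
        PgxAllele("*17", "increased", _f(0.015, 0.18, 0.03)),
    ),
    "CYP2D6": (
        PgxAllele("*1", "normal", _f(0.515, 0.76, 0.685)),
        PgxAllele("*1x2", "increased", _f(0.005, 0.01, 0.005)),
        PgxAllele("*10", "decreased", _f(0.42, 0.12, 0.25)),
        PgxAllele("*4", "none", _f(0.01, 0.08, 0.02)),
        PgxAllele("*5", "none", _f(0.05, 0.03, 0.04)),
    ),
    "CYP3A5": (
        PgxAllele("*1", "normal", _f(0.28, 0.35, 0.38)),
        PgxAllele("*3", "none", _f(0.72, 0.65, 0.62)),
    ),
    "DPYD": (
        PgxAllele("ref", "normal", _f(0.9955, 0.9795, 0.997)),
        PgxAllele("HapB3", "decreased", _f(0.004, 0.02, 0.002)),
        PgxAllele("*2A", "none", _f(0.0005, 0.0005, 0.001)),
    ),
    "NUDT15": (
        PgxAllele("*1", "normal", _f(0.89, 0.93, 0.94)),
        PgxAllele("*3", "none", _f(0.11, 0.07, 0.06)),
    ),
    "SLCO1B1": (
        PgxAllele("*1", "normal", _f(0.88, 0.92, 0.91)),
        PgxAllele("*5", "decreased", _f(0.12, 0.08, 0.09)),
    ),
    "TPMT": (
        PgxAllele("*1", "normal", _f(0.98, 0.985, 0.975)),
        PgxAllele("*3C", "none", _f(0.02, 0.015, 0.025)),
    ),
    "UGT1A1": (
        PgxAllele("*1", "normal", _f(0.72, 0.55, 0.78)),
        PgxAllele("*6", "decreased", _f(0.16, 0.03, 0.10)),
        PgxAllele("*28", "decreased", _f(0.12, 0.42, 0.12)),
    ),
    "VKORC1": (
        PgxAllele("ref", "normal", _f(0.11, 0.85, 0.25)),
        PgxAllele("rs9923231", "decreased", _f(0.89, 0.15, 0.75)),
    ),
}

#: Pharmacogenes in which loss of function is the actionable mechanism;
#: the putative-LOF screen is restricted to these.
PGX_LOF_GENES: tuple[str, ...] = (
    "CYP2B6", "CYP2C9", "CYP2C19", "CYP2D6", "DPYD",
    "G6PD", "NUDT15", "SLCO1B1", "TPMT", "UGT1A1",
)

#: CDC Tier 1 condition -> (disease genes, relevant PGx gene, actionable
#: phenotypes for drugs used to treat the condition).
CDC_TIER1_MAP: dict[str, dict] = {
    "HBOC": {"genes": ("BRCA1", "BRCA2"), "pgx_gene": "CYP2D6",
             "pgx_phenotypes": ("IM", "PM")},
    "Lynch": {"genes": ("MLH1", "MSH2", "MSH6", "PMS2"), "pgx_gene": "UGT1A1",
              "pgx_phenotypes": ("IM", "PM")},
    "FH": {"genes": ("LDLR", "APOB", "PCSK9"), "pgx_gene": "SLCO1B1",
           "pgx_phenotypes": ("IM-risk", "high-risk")},
}


@dataclass
class SimConfig:
    """Dials of the synthetic cohort generator (ground truth is derived from
    the planted rosters; everything downstream has a known answer)."""

    seed: int = 0
    n_per_ancestry: dict[str, int] = field(
        default_factory=lambda: {"CH": 5502, "IND": 1941, "MY": 1608})
    K: int = 3
    admixture_concentration: float = 5.0
    fraction_admixed: float = 0.10
    mismatch_prob_admixed: float = 0.3
    female_fraction: float = 0.573
    planted_genes: tuple[PlantedGene, ...] = DEFAULT_GENES
    planted_specific_variants: tuple[PlantedSpecificVariant, ...] = \
        DEFAULT_SPECIFIC_VARIANTS
    planted_hotspots: tuple[PlantedHotspot, ...] = DEFAULT_HOTSPOTS
    planted_pgx: dict[str, tuple[PgxAllele, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PGX))
    plant_classifier_exercises: bool = True
    plant_svs: bool = True
    bad_call_rate: float = 0.005
    n_blocks: int = 40
    chrom_length: int = 250_000_000

    def validate(self) -> None:
        if self.K != 3:
            raise ConfigError("K is fixed at 3")
        if set(self.n_per_ancestry) != set(ANCESTRIES):
            raise ConfigError(f"n_per_ancestry must cover {ANCESTRIES}")
        if any(n <= 0 for n in self.n_per_ancestry.values()):
            raise ConfigError("group sizes must be positive")
        if not (0.0 <= self.fraction_admixed <= 1.0):
            raise ConfigError("fraction_admixed must lie in [0, 1]")
        if self.admixture_concentration <= 0:
            raise ConfigError("admixture_concentration must be positive")
        genes = [g.gene for g in self.planted_genes]
        if len(genes) != len(set(genes)):
            raise ConfigError("duplicate gene in planted_genes")
        by_gene = {g.gene: g for g in self.planted_genes}
        for g in self.planted_genes:
            for anc, f_ in g.carrier_freq.items():
                if anc not in ANCESTRIES or not (0.0 <= f_ <= 1.0):
                    raise ConfigError(f"bad carrier frequency for {g.gene}")
            if g.inheritance not in ("AD", "AR", "XL"):
                raise ConfigError(f"bad inheritance for {g.gene}")
        for sv in self.planted_specific_variants:
            if sv.ancestry not in ANCESTRIES:
                raise ConfigError(f"bad ancestry for specific variant {sv.gene}")
            if sv.gene not in by_gene:
                raise ConfigError(f"specific variant gene {sv.gene} not planted")
            if sv.allele_count < 1 or sv.n_discordant > sv.allele_count:
                raise ConfigError("bad specific-variant allele counts")
        for hs in self.planted_hotspots:
            if hs.gene not in by_gene:
                raise ConfigError(f"hotspot gene {hs.gene} not planted")
        for gene, alleles in self.planted_pgx.items():
            for anc in ANCESTRIES:
                total = sum(a.freq[anc] for a in alleles)
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"PGx allele frequencies for {gene}/{anc} sum to {total}")

    def scaled(self, n_per_ancestry: dict[str, int]) -> "SimConfig":
        """Same planted truth at a different cohort size."""
        return replace(self, n_per_ancestry=dict(n_per_ancestry))
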