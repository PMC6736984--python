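"""WGS-guided fine-mapping of QTL support intervals to candidate genes.

Starting from the founder variant table restricted to a QTL's support
interval, three filters mirror the strategy that turns a multi-megabase QTL
into a short candidate list:

1. variants whose alternate allele is shared by all founders are dropped
   (they cannot explain founder effect differences);
2. variants are kept only when their strain distribution pattern — the set
   of founders carrying the alternate allele — matches the high/low founder
   bipartition estimated from the QTL's allele effects (equality by default,
   subset containment behind a flag);
3. synonymous variants are removed and genes are ranked by best consequence
   tier: {missense, 5'UTR, 3'UTR} above other genic consequences, with
   intergenic records excluded from the gene list.

Every step updates a telescoping ledger (counts in = counts out + removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "VariantTable",
    "CandidateReport",
    "read_vcf",
    "drop_common_variants",
    "match_founder_pattern",
    "filter_and_rank_consequences",
    "finemap_interval",
]

TIER_TOP = {"missense", "5_prime_UTR", "3_prime_UTR"}
SYNONYM_MAP = {
    "missense_variant": "missense",
    "synonymous_variant": "synonymous",
    "5_prime_utr_variant": "5_prime_UTR",
    "3_prime_utr_variant": "3_prime_UTR",
    "intron_variant": "intronic",
    "intergenic_variant": "intergenic",
}


@dataclass
class VariantTable:
    """Founder-stratified biallelic variant records.

    ``df`` columns: chrom, pos (1-based), ref, alt, gene (empty string for
    intergenic), consequence, plus one 0/1 column per founder strain
    (-1 = missing call).
    """

    df: pd.DataFrame
    strains: list[str]
    ledger: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [s for s in self.strains if s not in self.df.columns]
        if missing:
            raise ValueError(f"founder columns absent from table: {missing}")
        if not self.ledger:
            self.ledger = [{"step": "input", "n_in": len(self.df), "n_out": len(self.df)}]

    def __len__(self) -> int:
        return len(self.df)

    def _step(self, name: str, out: pd.DataFrame) -> "VariantTable":
        ledger = self.ledger + [
            {"step": name, "n_in": len(self.df), "n_out": len(out),
             "n_removed": len(self.df) - len(out)}
        ]
        return VariantTable(df=out.reset_index(drop=True), strains=list(self.strains),
                            ledger=ledger)

    def alt_founders(self) -> pd.Series:
        """Per record: frozenset of founders carrying the alternate allele."""
        geno = self.df[self.strains].to_numpy()
        return pd.Series(
            [frozenset(s for s, g in zip(self.strains, row) if g == 1) for row in geno],
            index=self.df.index,
        )


@dataclass
class CandidateReport:
    """Ranked candidate genes with supporting variants and the filter ledger."""

    genes: pd.DataFrame  # gene, tier, n_variants, rank
    variants: pd.DataFrame
    ledger: list[dict]
    evidence: dict = field(default_factory=dict)  # free-text manual curation

    def __post_init__(self) -> None:
        if len(self.genes) and (self.genes["n_variants"] < 1).any():
            raise ValueError("every candidate gene needs >= 1 supporting variant")
        for prev, step in zip(self.ledger, self.ledger[1:]):
            if step["n_in"] != prev["n_out"]:
                raise ValueError("filter ledger does not telescope")

    @property
    def ranked_genes(self) -> list[str]:
        return list(self.genes["gene"])


def normalize_consequence(label: str) -> str:
    lab = str(label).strip()
    lab = SYNONYM_MAP.get(lab.lower(), lab)
    known = {"synonymous", "missense", "5_prime_UTR", "3_prime_UTR", "intergenic", "intronic"}
    if lab not in known:
        warnings.warn(f"unknown consequence label {label!r}; treated as mid-tier")
        return "intronic"
    return lab


def read_vcf(path, csq_key: str = "CSQ") -> VariantTable:
    """Read a founder VCF; consequence and gene parsed from INFO[csq_key]
    as "consequence|gene"."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strains = list(vcf.samples)
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic record at {rec.CHROM}:{rec.POS}; split upstream")
        csq = rec.INFO.get(csq_key) or "|"
        consequence, _, gene = csq.partition("|")
        gene = "" if gene in (".", "") else gene
        row = {
            "chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF, "alt": rec.ALT[0],
            "gene": gene, "consequence": normalize_consequence(consequence or "intergenic"),
        }
        for s, gt in zip(strains, rec.gt_types):
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            row[s] = {0: 0, 1: 1, 2: -1, 3: 1}[int(gt)]
        rows.append(row)
    cols = ["chrom", "pos", "ref", "alt", "gene", "consequence"] + strains
    df = pd.DataFrame(rows, columns=cols)
    return VariantTable(df=df, strains=strains)


def restrict_to_interval(v: VariantTable, chrom, start: int, end: int) -> VariantTable:
    """Records within [start, end] (1-based inclusive) on one chromosome."""
    m = (v.df["chrom"] == chrom) & (v.df["pos"] >= start) & (v.df["pos"] <= end)
    return v._step("interval", v.df.loc[m])


def drop_common_variants(v: VariantTable) -> VariantTable:
    """Remove records where every founder carries the alternate allele."""
    geno = v.df[v.strains].to_numpy()
    common = (geno == 1).all(axis=1)
    return v._step("drop_common", v.df.loc[~common])


def match_founder_pattern(
    v: VariantTable, bipartition: set | frozenset, containment: bool = False
) -> VariantTable:
    """Keep records whose strain distribution pattern matches the founder
    bipartition from the allele effects (or its complement).

    ``bipartition`` names the founders on one side of the high/low effect
    split.  With ``containment`` the alt-carrier set may be a non-empty
    subset of either side instead of an exact match.
    """
    bip = frozenset(bipartition)
    allf = frozenset(v.strains)
    if not bip or bip == allf or not bip <= allf:
        raise ValueError(
            f"bipartition must be a nonempty proper subset of founders {sorted(allf)}"
        )
    comp = allf - bip
    carriers = v.alt_founders()
    if containment:
        keep = carriers.apply(lambda c: len(c) > 0 and (c <= bip or c <= comp))
    else:
        keep = carriers.apply(lambda c: c == bip or c == comp)
    return v._step("founder_pattern", v.df.loc[keep.to_numpy()])


def filter_and_rank_consequences(v: VariantTable) -> CandidateReport:
    """Drop synonymous variants and rank genes by best consequence tier.

    Tier 0: missense / 5'UTR / 3'UTR; tier 1: other genic (intronic, unknown
    coding).  Intergenic records never contribute a gene.  Ties break by
    supporting-variant count (more first) then gene id.
    """
    df = v.df.copy()
    df["consequence"] = df["consequence"].map(normalize_consequence)
    kept = df[df["consequence"] != "synonymous"]
    v2 = v._step("drop_synonymous", kept)
    genic = v2.df[(v2.df["gene"] != "") & (v2.df["consequence"] != "intergenic")]
    v3 = v2._step("drop_intergenic", genic)

    rows = []
    for gene, sub in v3.df.groupby("gene"):
        tier = 0 if sub["consequence"].isin(TIER_TOP).any() else 1
        rows.append({"gene": gene, "tier": tier, "n_variants": len(sub)})
    genes = pd.DataFrame(rows, columns=["gene", "tier", "n_variants"])
    genes = genes.sort_values(
        ["tier", "n_variants", "gene"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    genes["rank"] = np.arange(1, len(genes) + 1)
    return CandidateReport(genes=genes, variants=v3.df, ledger=v3.ledger)


def finemap_interval(
    v: VariantTable,
    chrom,
    start: int,
    end: int,
    bipartition: set | frozenset | None = None,
    containment: bool = False,
) -> CandidateReport:
    """Full fine-mapping pass over one QTL support interval."""
    step = restrict_to_interval(v, chrom, start, end)
    step = drop_common_variants(step)
    if bipartition is not None:
        step = match_founder_pattern(step, bipartition, containment=containment)
    return filter_and_rank_consequences(step)
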