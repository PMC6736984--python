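"""Provenance-tracked gene-set algebra for multi-omics fine-mapping.

The candidate-gene funnel intersects evidence layers in order: genes inside
the QTL support interval, genes surviving the founder-variant filters,
differential-expression lists for the trait and for diet, and genes
correlated with trait-associated microbial/fungal modules.  Every set
carries a provenance record back to its raw inputs and the funnel emits a
telescoping ledger, so a final candidate can be traced through every filter
that let it survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "FunnelReport",
    "genes_in_interval",
    "intersect",
    "run_funnel",
    "venn_counts",
    "module_correlated_genes",
    "read_gene_list",
    "read_gff3_genes",
    "read_bed_genes",
]

log = logging.getLogger("ailgxe.integrate")


def _normalize_id(g: str) -> str:
    return str(g).strip()


@dataclass(frozen=True)
class GeneSet:
    """An identified gene set with provenance.

    Gene ids are whitespace-normalized; the provenance dict records the
    producing operation, its parameters, and the labels of parent sets.
    """

    ids: frozenset
    label: str
    provenance: tuple = ()  # tuple of (key, value) pairs; hashable

    @classmethod
    def build(cls, ids, label: str, source: str, parents=(), **params) -> "GeneSet":
        raw = [_normalize_id(g) for g in ids]
        uniq = frozenset(raw)
        if len(raw) != len(set(raw)):
            log.warning("gene set %s: %d duplicate ids collapsed", label, len(raw) - len(uniq))
        prov = (
            ("source", source),
            ("parents", tuple(parents)),
            ("params", tuple(sorted(params.items()))),
        )
        return cls(ids=uniq, label=label, provenance=prov)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, gene: str) -> bool:
        return _normalize_id(gene) in self.ids


@dataclass
class FunnelReport:
    """Ordered record of the funnel's stages and the final candidates."""

    steps: list[dict] = field(default_factory=list)
    final: GeneSet | None = None

    def add(self, operation: str, input_sizes: list[int], result: GeneSet) -> None:
        if len(result) != len(result.ids):
            raise AssertionError("reported size must equal id-list length")
        self.steps.append(
            {
                "operation": operation,
                "input_sizes": list(input_sizes),
                "output_size": len(result),
                "surviving": sorted(result.ids),
            }
        )
        self.final = result

    def sizes(self) -> list[int]:
        return [s["output_size"] for s in self.steps]


def read_gene_list(path, column: str | None = None) -> list[str]:
    """Gene ids from a TSV; first column by default, or a named column."""
    df = pd.read_csv(path, sep="\t")
    col = column or df.columns[0]
    return [_normalize_id(g) for g in df[col].dropna()]


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene intervals (chrom, start, end, gene_id; 1-based inclusive) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        rows.append({"chrom": feat.seqid, "start": feat.start, "end": feat.end,
                     "gene_id": _normalize_id(gid)})
    return pd.DataFrame(rows)


def read_bed_genes(path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open on disk -> 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene_id"], usecols=range(4))
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    df["gene_id"] = df["gene_id"].map(_normalize_id)
    return df


def genes_in_interval(annotation: pd.DataFrame, chrom, start: int, end: int) -> GeneSet:
    """Genes whose annotated span overlaps [start, end] (any overlap,
    1-based inclusive)."""
    if chrom not in set(annotation["chrom"]):
        raise ValueError(f"chromosome {chrom!r} absent from annotation")
    hit = annotation[
        (annotation["chrom"] == chrom)
        & (annotation["start"] <= end)
        & (annotation["end"] >= start)
    ]
    return GeneSet.build(
        hit["gene_id"], label=f"interval:{chrom}:{start}-{end}",
        source="genes_in_interval", chrom=str(chrom), start=start, end=end,
    )


def intersect(sets: list[GeneSet], label: str | None = None) -> GeneSet:
    """Exact intersection of >= 2 gene sets, provenance preserved."""
    if len(sets) < 2:
        raise ValueError("intersect needs at least 2 gene sets")
    ids = frozenset.intersection(*(s.ids for s in sets))
    return GeneSet.build(
        ids, label=label or " & ".join(s.label for s in sets),
        source="intersect", parents=[s.label for s in sets],
    )


def venn_counts(sets: list[GeneSet]) -> dict:
    """Membership counts for every non-empty combination of up to 5 sets."""
    if not (2 <= len(sets) <= 5):
        raise ValueError("venn_counts supports 2 to 5 sets")
    out = {}
    for k in range(1, len(sets) + 1):
        for combo in combinations(range(len(sets)), k):
            inside = frozenset.intersection(*(sets[i].ids for i in combo))
            outside = frozenset.union(
                *(sets[i].ids for i in range(len(sets)) if i not in combo)
            ) if len(combo) < len(sets) else frozenset()
            key = "&".join(sets[i].label for i in combo)
            out[key] = len(inside - outside)
    return out


def module_correlated_genes(
    expression: pd.DataFrame, eigen_profile: np.ndarray, alpha: float = 0.05
) -> GeneSet:
    """Genes whose expression rank-correlates with a module eigenOTU.

    Spearman per gene against the eigenOTU profile over shared samples, BH
    adjustment across genes, membership at adjusted p < alpha.  A simple
    stand-in for externally computed module-correlated DE lists.
    """
    e = np.asarray(eigen_profile, dtype=float)
    if expression.shape[1] != len(e):
        raise ValueError("expression columns must align with the eigenOTU profile")
    pvals, genes = [], []
    for gene, row in expression.iterrows():
        rho, p = stats.spearmanr(row.to_numpy(dtype=float), e)
        genes.append(gene)
        pvals.append(1.0 if np.isnan(p) else p)
    padj = multipletests(pvals, method="fdr_bh")[1]
    hits = [g for g, p in zip(genes, padj) if p < alpha]
    return GeneSet.build(hits, label="module-correlated", source="module_correlated_genes",
                         alpha=alpha, n_genes_tested=len(genes))


def run_funnel(stages: list[tuple[str, GeneSet]]) -> FunnelReport:
    """Apply intersection stages in order, recording the telescoping ledger.

    ``stages`` is an ordered list of (stage name, gene set); the first stage
    seeds the funnel (typically the QTL interval genes) and each later set is
    intersected with the running survivors.  An empty stage set empties the
    funnel but is recorded, not an error.
    """
    if not stages:
        raise ValueError("funnel needs at least one stage")
    report = FunnelReport()
    name0, current = stages[0]
    report.add(name0, [len(current)], current)
    for name, gs in stages[1:]:
        if gs is None:
            raise ValueError(f"stage {name!r} references an unknown gene set")
        nxt = intersect([current, gs], label=f"{current.label} & {gs.label}")
        report.add(name, [len(current), len(gs)], nxt)
        current = nxt
    return report
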