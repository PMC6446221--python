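"""Variant-source contribution decomposition.

For a gene category and a ranking, the relative contribution of SNP,
CNV-gain and CNV-loss evidence is summarized as a barycentric point: per
source, take a quantile (default the 75% quantile) of the -log10 gene-level
p-values over the category's genes, then normalize the three quantiles to
sum to one.  Categories with no evidence in any source are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ContributionPoint", "SOURCES", "source_matrix", "category_contribution",
           "contribution_table"]

SOURCES = ("snp", "gain", "loss")


@dataclass
class ContributionPoint:
    w_snp: float
    w_gain: float
    w_loss: float
    category: str
    ranking: str
    q: float
    no_evidence: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.w_snp, self.w_gain, self.w_loss])


def source_matrix(gene_p: pd.DataFrame) -> pd.DataFrame:
    """Gene x source matrix of -log10 p (missing evidence -> 0).

    ``gene_p`` carries columns p_snp, p_gain, p_loss (NaN where the gene
    overlaps no unit of that source).  Zero p-values are capped at the
    smallest positive float with a warning.
    """
    out = {}
    for src in SOURCES:
        col = gene_p.get(f"p_{src}")
        if col is None:
            out[src] = np.zeros(len(gene_p))
            continue
        p = col.to_numpy(dtype=float)
        if np.any(p == 0):
            warnings.warn(f"p=0 in source {src}; capping at machine minimum",
                          stacklevel=2)
            p = np.where(p == 0, np.finfo(float).tiny, p)
        out[src] = np.where(np.isfinite(p), -np.log10(p), 0.0)
    idx = gene_p["gene_id"] if "gene_id" in gene_p else gene_p.index
    return pd.DataFrame(out, index=pd.Index(idx, name="gene_id"))


def category_contribution(
    rows: pd.DataFrame, category: str = "all", ranking: str = "", q: float = 0.75
) -> ContributionPoint:
    """Barycentric source contributions for one gene category.

    Per source, the q-quantile of -log10 p over the category's genes; the
    three quantiles normalized to sum 1.  Needs at least 4 genes.
    """
    if len(rows) < 4:
        raise ValueError("need at least 4 genes in the category")
    quants = np.array([float(np.quantile(rows[src], q)) for src in SOURCES])
    total = quants.sum()
    if total <= 0:
        return ContributionPoint(0.0, 0.0, 0.0, category, ranking, q, no_evidence=True)
    w = quants / total
    return ContributionPoint(*w.tolist(), category=category, ranking=ranking, q=q)


def contribution_table(
    gene_p: pd.DataFrame,
    genes: pd.DataFrame,
    ranking: str = "",
    q: float = 0.75,
    category_cols: tuple[str, ...] = ("orf_class", "tf_superfamily"),
) -> pd.DataFrame:
    """Contribution points for all genes plus each gene category level."""
    mat = source_matrix(gene_p).reset_index()
    merged = mat.merge(genes[["gene_id", *category_cols]], on="gene_id", how="left")
    points = [category_contribution(merged, "all", ranking, q)]
    for col in category_cols:
        for val, grp in merged.groupby(col):
            if not val or len(grp) < 4:
                continue
            points.append(category_contribution(grp, f"{col}={val}", ranking, q))
    return pd.DataFrame(
        [
            {"category": p.category, "ranking": p.ranking, "q": p.q,
             "w_snp": p.w_snp, "w_gain": p.w_gain, "w_loss": p.w_loss,
             "no_evidence": p.no_evidence}
            for p in points
        ]
    )
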