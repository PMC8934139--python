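"""Pathway-level aggregation of probe BMDs and the BEPOD point of departure.

Probe-level BMD estimates are first collapsed to genes (multi-gene probes
removed; multiple probes per gene averaged), then summarized per gene-set
category: min/max/mean/median BMD over the dose-responsive genes in the
category, a two-tailed Fisher exact enrichment p-value (genes with vs.
without BMD estimates, inside vs. outside the category), and the responsive
percentage. Categories passing p < 0.05, more than one responsive gene, and
percentage >= 3% are *enriched*; the median of the enriched categories'
median BMDs is the biological-effect point of departure (BEPOD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GeneAnnotation

__all__ = ["PathwayResult", "BepodResult", "map_probes_to_genes",
           "aggregate_categories", "fisher_enrichment", "percentage",
           "select_enriched", "compute_bepod", "correlate_pod", "cdc_table",
           "pathway_analysis"]


@dataclass
class BepodResult:
    """BEPOD and the enriched categories it was derived from."""

    bepod: float | None
    enriched_categories: list
    p_cutoff: float
    min_genes: int
    min_percentage: float

    @property
    def defined(self) -> bool:
        return self.bepod is not None


def map_probes_to_genes(estimates: pd.DataFrame,
                        annotation: GeneAnnotation | Mapping[str, set],
                        ) -> pd.DataFrame:
    """Collapse probe-level BMD estimates to gene level.

    Probes mapping to more than one gene are removed; probes without a mapping
    are dropped; when several probes map to one gene the gene's BMD (and
    BMDL/BMDU) is the arithmetic mean across those probes. ``estimates`` needs
    columns probe_id, bmd, bmdl, bmdu.
    """
    p2g = annotation.probe_to_genes if isinstance(annotation, GeneAnnotation) \
        else dict(annotation)
    if not p2g:
        raise ValueError("empty annotation")
    rows = []
    for rec in estimates.itertuples(index=False):
        genes = p2g.get(rec.probe_id)
        if genes is None or len(genes) != 1:
            continue  # unmapped or multi-gene probe
        rows.append({"gene_id": next(iter(genes)), "bmd": rec.bmd,
                     "bmdl": rec.bmdl, "bmdu": rec.bmdu})
    if not rows:
        return pd.DataFrame(columns=["gene_id", "bmd", "bmdl", "bmdu"])
    return (pd.DataFrame(rows)
            .groupby("gene_id", as_index=False)[["bmd", "bmdl", "bmdu"]]
            .mean())


def fisher_enrichment(with_in: int, without_in: int,
                      with_out: int, without_out: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table

        [[genes with BMD in category,    genes without BMD in category],
         [genes with BMD outside,        genes without BMD outside]]

    summing all hypergeometric tables at most as probable as the observed one.
    """
    table = np.array([[with_in, without_in], [with_out, without_out]])
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def percentage(genes_with_bmd_in: int, genes_total_in: int) -> float:
    """Fraction of a category's genes that carry a BMD estimate."""
    if genes_total_in < 1:
        raise ValueError("category has no genes")
    return genes_with_bmd_in / genes_total_in


def aggregate_categories(gene_table: pd.DataFrame,
                         annotation: GeneAnnotation,
                         universe: set | None = None) -> pd.DataFrame:
    """Per-category BMD statistics and enrichment tests.

    The Fisher universe defaults to all uniquely-mapped genes on the platform
    annotation. Categories with zero responsive genes carry NaN BMD statistics
    (but still get an enrichment p-value). Returns one row per category with
    columns: category_id, name, genes_total, genes_with_bmd, p_fisher,
    percentage, bmd_min, bmd_max, bmd_mean, bmd_median, bmdl_median,
    bmdu_median.
    """
    if not annotation.categories:
        raise ValueError("no categories")
    if universe is None:
        universe = annotation.universe or set(gene_table["gene_id"])
    with_bmd = set(gene_table["gene_id"]) & universe
    n_with = len(with_bmd)
    n_universe = len(universe)
    bmd_by_gene = gene_table.set_index("gene_id")

    rows = []
    for cid in sorted(annotation.categories):
        name, genes = annotation.categories[cid]
        members = set(genes) & universe
        if not members:
            continue
        hit = members & with_bmd
        k, m = len(hit), len(members)
        p = fisher_enrichment(k, m - k, n_with - k, (n_universe - m) - (n_with - k))
        row = {"category_id": cid, "name": name, "genes_total": m,
               "genes_with_bmd": k, "p_fisher": p,
               "percentage": percentage(k, m),
               "bmd_min": np.nan, "bmd_max": np.nan, "bmd_mean": np.nan,
               "bmd_median": np.nan, "bmdl_median": np.nan, "bmdu_median": np.nan}
        if k:
            sub = bmd_by_gene.loc[sorted(hit)]
            row.update(bmd_min=float(sub["bmd"].min()),
                       bmd_max=float(sub["bmd"].max()),
                       bmd_mean=float(sub["bmd"].mean()),
                       bmd_median=float(sub["bmd"].median()),
                       bmdl_median=float(sub["bmdl"].median()),
                       bmdu_median=float(sub["bmdu"].median()))
        rows.append(row)
    return pd.DataFrame(rows)


def select_enriched(results: pd.DataFrame, p_cutoff: float = 0.05,
                    min_genes: int = 1, min_percentage: float = 0.03,
                    ) -> pd.DataFrame:
    """Enriched categories: p < p_cutoff (strict), genes_with_bmd > min_genes
    (strict), percentage >= min_percentage (inclusive)."""
    mask = ((results["p_fisher"] < p_cutoff)
            & (results["genes_with_bmd"] > min_genes)
            & (results["percentage"] >= min_percentage))
    return results.loc[mask].reset_index(drop=True)


def compute_bepod(enriched: pd.DataFrame, p_cutoff: float = 0.05,
                  min_genes: int = 1, min_percentage: float = 0.03,
                  ) -> BepodResult:
    """BEPOD = median over enriched categories of their median BMD.

    With an even number of categories the median is the mean of the middle
    two. An empty enriched set yields an explicit "no BEPOD" result.
    """
    if len(enriched) == 0:
        return BepodResult(None, [], p_cutoff, min_genes, min_percentage)
    med = float(enriched["bmd_median"].median())
    return BepodResult(med, enriched["category_id"].tolist(),
                       p_cutoff, min_genes, min_percentage)


def pathway_analysis(estimates: pd.DataFrame, annotation: GeneAnnotation,
                     p_cutoff: float = 0.05, min_genes: int = 1,
                     min_percentage: float = 0.03):
    """End-to-end pathway stage: gene mapping, category statistics, enrichment
    filtering, BEPOD. Returns ``(category_table, BepodResult)``."""
    gene_table = map_probes_to_genes(estimates, annotation)
    table = aggregate_categories(gene_table, annotation)
    enriched = select_enriched(table, p_cutoff, min_genes, min_percentage)
    bepod = compute_bepod(enriched, p_cutoff, min_genes, min_percentage)
    return table, bepod


def correlate_pod(bepods: Sequence[float], pods: Sequence[float]) -> tuple:
    """Pearson r and RMSD between paired PODs on the log10 scale."""
    b = np.asarray(bepods, dtype=float)
    p = np.asarray(pods, dtype=float)
    if b.shape != p.shape or b.size < 2:
        raise ValueError("need at least 2 paired values")
    if np.any(b <= 0) or np.any(p <= 0):
        raise ValueError("PODs must be positive for the log10 comparison")
    lb, lp = np.log10(b), np.log10(p)
    r = float(stats.pearsonr(lb, lp)[0])
    rmsd = float(np.sqrt(np.mean((lb - lp) ** 2)))
    return r, rmsd


def cdc_table(values: Sequence[float]) -> pd.DataFrame:
    """Empirical cumulative distribution points (value, cumulative fraction),
    with duplicated values collapsed into one step of combined mass."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("no values")
    uniq, counts = np.unique(v, return_counts=True)
    frac = np.cumsum(counts) / v.size
    return pd.DataFrame({"value": uniq, "cumulative_fraction": frac})
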