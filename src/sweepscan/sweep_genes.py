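"""Sweep-gene calling: block-to-gene mapping, two-method intersection,
hypergeometric enrichment.

The intersection rule combines the two scans: set A holds genes whose
per-gene Fst score exceeds a strict threshold (default 0.9), set B the union
over scan directions of the top-N genes ranked by the composite-likelihood
score of overlapping blocks (default N = 500); genes in both sets are the
robust sweep candidates.  Enrichment of a gene set against user-supplied
term-to-gene maps uses the upper-tail hypergeometric test with
Benjamini-Hochberg adjustment across terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sweepscan.core_io import GeneModel

logger = logging.getLogger(__name__)


@dataclass
class SweepGeneSet:
    method: str  # "fst" | "xpclr" | "intersection"
    direction: str  # population label or "both"
    genes: pd.DataFrame  # gene_id plus score column(s)
    provenance: str

    def __post_init__(self):
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique within a set")

    @property
    def gene_ids(self) -> set[str]:
        return set(self.genes["gene_id"])


def map_blocks_to_genes(blocks: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Genes overlapping any block by >= 1 bp, with each gene's best clr.

    ``blocks`` needs columns contig, start, end and (optionally) clr; a
    gene's score is the max clr over blocks it overlaps (NaN without a clr
    column).
    """
    has_clr = "clr" in blocks.columns
    rows = []
    by_contig: dict[str, pd.DataFrame] = {
        str(ct): grp for ct, grp in blocks.groupby("contig")
    }
    for g in genes:
        grp = by_contig.get(g.contig)
        if grp is None:
            continue
        hit = (grp["start"] <= g.end) & (grp["end"] >= g.start)
        if hit.any():
            score = float(grp.loc[hit, "clr"].max()) if has_clr else float("nan")
            rows.append((g.gene_id, g.contig, g.start, g.end, int(hit.sum()), score))
    return pd.DataFrame(
        rows, columns=["gene_id", "contig", "start", "end", "n_blocks", "clr"]
    )


def xpclr_gene_table(
    blocks: pd.DataFrame, genes: list[GeneModel]
) -> pd.DataFrame:
    """Per-direction gene ranking by max block clr over overlapping blocks."""
    out = []
    for direction, grp in blocks.groupby("direction", sort=True):
        mapped = map_blocks_to_genes(grp, genes)
        mapped["direction"] = direction
        out.append(mapped)
    if not out:
        return pd.DataFrame(
            columns=["gene_id", "contig", "start", "end", "n_blocks", "clr", "direction"]
        )
    return pd.concat(out, ignore_index=True)


def top_xpclr_genes(gene_table: pd.DataFrame, top_n: int, mode: str = "union") -> pd.DataFrame:
    """Top genes by clr across directions.

    ``union`` mode ranks the per-direction tables jointly and truncates the
    deduplicated union to ``top_n`` genes (a gene scored in both directions
    keeps its higher clr).  ``per-direction`` mode takes ``top_n`` genes from
    each direction and unions them (the result may exceed ``top_n``).
    """
    if gene_table.empty:
        return gene_table.copy()
    if mode == "union":
        best = (
            gene_table.sort_values(["clr", "gene_id"], ascending=[False, True], kind="mergesort")
            .drop_duplicates("gene_id", keep="first")
        )
        return best.head(top_n).reset_index(drop=True)
    if mode == "per-direction":
        parts = []
        for _, grp in gene_table.groupby("direction", sort=True):
            grp = grp.sort_values(["clr", "gene_id"], ascending=[False, True], kind="mergesort")
            parts.append(grp.head(top_n))
        merged = pd.concat(parts, ignore_index=True)
        merged = merged.sort_values(["clr", "gene_id"], ascending=[False, True], kind="mergesort")
        return merged.drop_duplicates("gene_id", keep="first").reset_index(drop=True)
    raise ValueError("mode must be 'union' or 'per-direction'")


def intersect_sweeps(
    fst_genes: pd.DataFrame,
    xpclr_genes: pd.DataFrame,
    fst_threshold: float = 0.9,
    xpclr_top_n: int = 500,
    mode: str = "union",
) -> SweepGeneSet:
    """Two-method intersection of sweep candidates.

    Set A: genes with Fst ``score`` strictly above ``fst_threshold``.
    Set B: the top ``xpclr_top_n`` genes by clr (see :func:`top_xpclr_genes`).
    Returns A intersect B with both scores attached.
    """
    a = fst_genes[fst_genes["score"] > fst_threshold]
    b = top_xpclr_genes(xpclr_genes, xpclr_top_n, mode=mode)
    if a.empty or b.empty:
        logger.warning("empty parent set (Fst: %d genes, XP-CLR: %d)", len(a), len(b))
    merged = a[["gene_id", "score"]].merge(
        b[["gene_id", "clr"]], on="gene_id", how="inner"
    )
    merged = merged.rename(columns={"score": "fst"}).sort_values("gene_id").reset_index(drop=True)
    return SweepGeneSet(
        method="intersection",
        direction="both",
        genes=merged,
        provenance=f"fst>{fst_threshold} AND xpclr top {xpclr_top_n} ({mode})",
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (bounded by 1)."""
    p = np.asarray(p, dtype=np.float64)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def hypergeom_enrich(
    selected: set[str],
    background: set[str],
    term_map: dict[str, set[str]],
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``selected`` within
    ``background`` for every term, BH-adjusted across terms.

    Term gene sets are intersected with the background first; terms empty
    after that are dropped.  Rows are sorted by p then term id.
    """
    if not selected <= background:
        raise ValueError("selected genes must be a subset of the background")
    n_bg = len(background)
    n_sel = len(selected)
    rows = []
    for term, genes in sorted(term_map.items()):
        in_bg = genes & background
        big_k = len(in_bg)
        if big_k == 0:
            continue
        k = len(in_bg & selected)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_sel))
        rows.append((term, (term_names or {}).get(term, ""), k, big_k, n_sel, n_bg, p))
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"]
    )
    if not df.empty:
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = []
    return df


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV ``term_id<TAB>gene_id`` into a term -> gene-set map."""
    term_map: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, gene = line.split("\t")[:2]
            term_map.setdefault(term, set()).add(gene)
    return term_map
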