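"""Diversity and differentiation statistics.

Per-site Fst follows the Weir-Cockerham (1984) variance-components estimator
for two populations.  With ``n_i`` individuals carrying called genotypes,
alt-allele frequency ``p_i`` and observed heterozygote fraction ``h_i`` in
population ``i``:

    nbar = (n1 + n2) / 2
    n_c  = 2*nbar - (n1^2 + n2^2) / (2*nbar)
    pbar = (n1*p1 + n2*p2) / (2*nbar)
    s2   = sum_i n_i (p_i - pbar)^2 / nbar
    hbar = (n1*h1 + n2*h2) / (2*nbar)
    a = (nbar/n_c) * [s2 - (1/(nbar-1)) * (pbar(1-pbar) - s2/2 - hbar/4)]
    b = (nbar/(nbar-1)) * [pbar(1-pbar) - s2/2 - ((2*nbar-1)/(4*nbar)) * hbar]
    c = hbar / 2
    theta = a / (a + b + c)

theta is undefined (NaN, never 0) when a + b + c == 0, i.e. the site is
monomorphic across both populations.  Negative estimates are retained in
tables (standard estimator behaviour) and clipped to 0 only before the
Fisher z-transform.

Nucleotide diversity per site is the unbiased pairwise-difference fraction
``(n^2 - c0^2 - c1^2) / (n (n-1))`` over called alleles; windowed pi sums
site values over fixed-length windows and divides by the window length, so
monomorphic positions contribute implicitly through the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sweepscan.core_io import GeneModel, PopulationAssignment, VariantTable, VariantSite


@dataclass(frozen=True)
class FstComponents:
    n1: int
    n2: int
    p1: float
    p2: float
    h1: float
    h2: float
    a: float
    b: float
    c: float
    theta: float  # NaN when a+b+c == 0


def _wc_components(n1, n2, p1, p2, h1, h2):
    """Vectorised Weir-Cockerham components for r=2; inputs broadcastable."""
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    nbar = (n1 + n2) / 2.0
    nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
    pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
    inner = pbar * (1.0 - pbar) - s2 / 2.0
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0.0, a / np.where(denom != 0.0, denom, 1.0), np.nan)
    return a, b, c, theta


def _pop_stats(gt: np.ndarray, cols: np.ndarray):
    """Per-site (n, p, h) for the samples in ``cols`` of a biallelic table."""
    sub = gt[:, cols, :]
    called = (sub >= 0).all(axis=2)
    n = called.sum(axis=1)
    alt = np.where(called, sub.sum(axis=2), 0)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, alt.sum(axis=1) / (2.0 * np.maximum(n, 1)), np.nan)
    het = called & (sub[:, :, 0] != sub[:, :, 1])
    with np.errstate(invalid="ignore"):
        h = np.where(n > 0, het.sum(axis=1) / np.maximum(n, 1), np.nan)
    return n, p, h


def site_fst_wc(site: VariantSite, samples: list[str], pops: PopulationAssignment) -> FstComponents:
    """Weir-Cockerham components for a single biallelic site."""
    if not site.is_biallelic:
        raise ValueError("site_fst_wc requires a biallelic site")
    gt = site.genotypes[None, :, :]
    i1 = pops.indices(samples, pops.obj_label)
    i2 = pops.indices(samples, pops.ref_label)
    (n1,), (p1,), (h1,) = _pop_stats(gt, i1)
    (n2,), (p2,), (h2,) = _pop_stats(gt, i2)
    if n1 == 0 or n2 == 0:
        raise ValueError("both populations need at least one called genotype")
    a, b, c, theta = _wc_components(n1, n2, p1, p2, h1, h2)
    return FstComponents(int(n1), int(n2), float(p1), float(p2), float(h1), float(h2),
                         float(a), float(b), float(c), float(theta))


def fst_table(table: VariantTable, pops: PopulationAssignment) -> pd.DataFrame:
    """Per-site Weir-Cockerham Fst over a biallelic table.

    Sites where either population has no called genotype are skipped (left
    out of the result) with their count reported in the ``attrs``.
    """
    gt = table.genotypes
    i1 = pops.indices(table.samples, pops.obj_label)
    i2 = pops.indices(table.samples, pops.ref_label)
    n1, p1, h1 = _pop_stats(gt, i1)
    n2, p2, h2 = _pop_stats(gt, i2)
    ok = (n1 > 0) & (n2 > 0)
    a, b, c, theta = _wc_components(n1[ok], n2[ok], p1[ok], p2[ok], h1[ok], h2[ok])
    df = pd.DataFrame(
        {
            "contig": [table.contigs[i] for i in table.contig_idx[ok]],
            "pos": table.pos[ok],
            "n1": n1[ok],
            "n2": n2[ok],
            "p1": p1[ok],
            "p2": p2[ok],
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
        }
    )
    df.attrs["n_skipped"] = int((~ok).sum())
    return df


def genomewide_fst(fst: pd.DataFrame, method: str = "weighted") -> float:
    """Multi-locus Fst over a per-site component table.

    ``weighted`` (default) is the standard Weir-Cockerham multi-locus
    estimator, sum(a) / sum(a+b+c) — the ratio of summed variance components,
    unbiased under the drift model.  ``per-site`` is the plain mean of the
    per-site ratios, which Jensen's inequality biases downward; it is kept
    because per-site summaries are sometimes reported that way.
    """
    a = fst["a"].to_numpy()
    denom = (fst["a"] + fst["b"] + fst["c"]).to_numpy()
    if method == "weighted":
        return float(a[denom != 0].sum() / denom[denom != 0].sum())
    if method == "per-site":
        return float(np.nanmean(fst["theta"].to_numpy()))
    raise ValueError("method must be 'weighted' or 'per-site'")


def z_transform_fst(values, method: str = "fisher") -> np.ndarray:
    """Monotone transform of per-site theta for Manhattan-plot scaling.

    ``fisher``: atanh after clipping negatives to 0 and values to 1 - 1e-12.
    ``zscore``: (x - mean) / sd with the sample standard deviation (ddof=1).
    Both are strictly monotone on [0, 1), so rank-based sweep calls are
    invariant to the choice.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        return x.copy()
    if method == "fisher":
        clipped = np.clip(x, 0.0, 1.0 - 1e-12)
        return np.arctanh(clipped)
    if method == "zscore":
        sd = np.std(x, ddof=1) if x.size > 1 else 0.0
        return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)
    raise ValueError(f"unknown method {method!r}")


def genes_for_sites(
    contigs: list[str], contig_idx: np.ndarray, pos: np.ndarray, genes: list[GeneModel]
):
    """Yield (gene, site-index array) for every gene containing >= 1 site."""
    by_contig: dict[str, np.ndarray] = {}
    for ci, name in enumerate(contigs):
        by_contig[name] = np.flatnonzero(contig_idx == ci)
    for g in genes:
        idx = by_contig.get(g.contig)
        if idx is None or idx.size == 0:
            continue
        p = pos[idx]
        lo = np.searchsorted(p, g.start, side="left")
        hi = np.searchsorted(p, g.end, side="right")
        if hi > lo:
            yield g, idx[lo:hi]


def gene_fst(
    fst: pd.DataFrame,
    genes: list[GeneModel],
    contigs: list[str] | None = None,
    aggregator: str = "max",
) -> pd.DataFrame:
    """Aggregate per-site theta to genes (default: max over member SNPs).

    A SNP inside two overlapping genes contributes to both; genes with no
    SNPs are omitted.  ``contigs`` fixes the contig order used downstream for
    deterministic tie-breaking (defaults to order of appearance in ``fst``).
    """
    if aggregator not in ("max", "mean"):
        raise ValueError("aggregator must be 'max' or 'mean'")
    if contigs is None:
        contigs = list(dict.fromkeys(fst["contig"]))
    order = {c: i for i, c in enumerate(contigs)}
    contig_idx = fst["contig"].map(order).to_numpy()
    pos = fst["pos"].to_numpy()
    theta = fst["theta"].to_numpy()
    rows = []
    for g, idx in genes_for_sites(contigs, contig_idx, pos, genes):
        vals = theta[idx]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        score = float(vals.max()) if aggregator == "max" else float(vals.mean())
        rows.append((g.gene_id, g.contig, g.start, g.end, idx.size, score))
    return pd.DataFrame(
        rows, columns=["gene_id", "contig", "start", "end", "n_snps", "score"]
    )


def top_fraction(
    scores: pd.DataFrame,
    q: float,
    contigs: list[str] | None = None,
    score_col: str = "score",
) -> pd.DataFrame:
    """The ceil(q*N) highest-scoring rows, deterministically tie-broken.

    Ties at the cut resolve by (score desc, contig order, position, gene_id).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("fraction must lie in (0,1)")
    n = len(scores)
    if n == 0:
        return scores.copy()
    if contigs is None:
        contigs = list(dict.fromkeys(scores["contig"]))
    order = {c: i for i, c in enumerate(contigs)}
    df = scores.copy()
    df["_contig_order"] = df["contig"].map(order)
    pos_col = "start" if "start" in df.columns else "pos"
    sort_cols = [score_col, "_contig_order", pos_col]
    ascending = [False, True, True]
    if "gene_id" in df.columns:
        sort_cols.append("gene_id")
        ascending.append(True)
    df = df.sort_values(sort_cols, ascending=ascending, kind="mergesort")
    k = math.ceil(q * n)
    return df.head(k).drop(columns=["_contig_order"])


def site_pi(c0: int, c1: int) -> float:
    """Pairwise-difference fraction at one site from allele counts.

    ``(n^2 - c0^2 - c1^2) / (n (n-1))`` with ``n = c0 + c1``; requires
    ``n >= 2``.
    """
    n = c0 + c1
    if n < 2:
        raise ValueError("site_pi needs at least two called alleles")
    return (n * n - c0 * c0 - c1 * c1) / (n * (n - 1))


@dataclass(frozen=True)
class WindowPi:
    contig: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    n_variant_sites: int
    pi: float  # per-bp


def windowed_pi(
    table: VariantTable,
    pops: PopulationAssignment | None = None,
    label: str | None = None,
    window_bp: int = 20_000,
) -> list[WindowPi]:
    """Per-bp nucleotide diversity in non-overlapping windows.

    With ``pops``/``label`` given, alleles are counted within that population
    only.  Every window is reported, including SNP-free ones (pi = 0); the
    last partial window is divided by its actual length.  Sites with fewer
    than two called alleles are skipped.
    """
    gt = table.genotypes
    if pops is not None:
        cols = pops.indices(table.samples, label or pops.obj_label)
        gt = gt[:, cols, :]
    called = (gt >= 0).all(axis=2)
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, gt.sum(axis=2), 0).sum(axis=1)
    c1 = alt
    c0 = n_alleles - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(
            n_alleles >= 2,
            (n_alleles.astype(np.float64) ** 2 - c0.astype(np.float64) ** 2 - c1.astype(np.float64) ** 2)
            / (n_alleles * np.maximum(n_alleles - 1, 1)),
            0.0,
        )
    out: list[WindowPi] = []
    for ci, contig in enumerate(table.contigs):
        length = table.contig_lengths.get(contig)
        if length is None:
            raise ValueError(f"unknown length for contig {contig!r}")
        sel = table.contig_idx == ci
        positions = table.pos[sel]
        vals = pi_site[sel]
        informative = n_alleles[sel] >= 2
        n_windows = math.ceil(length / window_bp)
        win_of = (positions - 1) // window_bp
        sums = np.bincount(win_of[informative], weights=vals[informative], minlength=n_windows)
        counts = np.bincount(win_of[informative], minlength=n_windows)
        for w in range(n_windows):
            start = w * window_bp + 1
            end = min((w + 1) * window_bp, length)
            out.append(
                WindowPi(contig, start, end, int(counts[w]), float(sums[w] / (end - start + 1)))
            )
    return out


def compare_pi(group_a: list[WindowPi], group_b: list[WindowPi]):
    """Two-group comparison of window pi: means, medians, rank-sum p.

    Returns a dict with per-group mean/median and the two-sided Wilcoxon
    rank-sum p-value (NaN if either group has fewer than two windows).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    a = np.asarray([w.pi for w in group_a])
    b = np.asarray([w.pi for w in group_b])
    if len(a) < 2 or len(b) < 2:
        p = float("nan")
    else:
        p = float(stats.ranksums(a, b).pvalue)
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "p_value": p,
    }
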