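"""Population structure summaries and phylogeny plumbing.

* Genotype PCA with Patterson-style sqrt(p(1-p)) scaling and a shrunk allele
  frequency so near-fixed sites never divide by zero.
* SNP-supermatrix export: heterozygotes become IUPAC ambiguity codes,
  missing genotypes 'N', written as relaxed PHYLIP one sample-row at a time.
* An allele-sharing distance plus a Saitou-Nei neighbor-joining tree as an
  internal, fully testable surrogate for external maximum-likelihood runs,
  whose output support values can be post-processed here
  (:func:`collapse_low_support`).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from sweepscan.core_io import VariantTable

_IUPAC = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
}


@dataclass
class PcaResult:
    samples: list[str]
    coordinates: np.ndarray  # (n_samples, k)
    explained: np.ndarray  # (k,) fractions of total variance


def genotype_pca(dosage: np.ndarray, samples: list[str], k: int = 10) -> PcaResult:
    """PCA of a (n_samples, n_sites) dosage matrix (NaN = missing).

    Missing dosages are mean-imputed per site; each site is centered and
    scaled by sqrt(phat (1 - phat)) with the shrunk frequency
    ``phat = (1 + sum dosage) / (2 + 2 n_called)``.  Coordinates come from
    the SVD of the scaled matrix (equivalently, eigendecomposition of the
    sample covariance); explained-variance fractions are non-increasing and
    sum to at most 1.
    """
    x = np.array(dosage, dtype=np.float64)
    n, s = x.shape
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    k = min(k, n)
    called = ~np.isnan(x)
    n_called = called.sum(axis=0)
    col_sum = np.nansum(x, axis=0)
    with np.errstate(invalid="ignore"):
        col_mean = np.where(n_called > 0, col_sum / np.maximum(n_called, 1), 0.0)
    idx = np.nonzero(~called)
    x[idx] = col_mean[idx[1]]
    phat = (1.0 + col_sum) / (2.0 + 2.0 * n_called)
    scale = np.sqrt(phat * (1.0 - phat))
    x = (x - col_mean) / scale
    if not np.isfinite(x).all() or float(np.abs(x).max(initial=0.0)) == 0.0:
        raise ValueError("zero-variance genotype matrix")
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    total = float((sv**2).sum())
    coords = u[:, :k] * sv[:k]
    explained = sv[:k] ** 2 / total
    return PcaResult(list(samples), coords, explained)


@dataclass
class SnpAlignment:
    """One IUPAC-coded sequence per sample over the ordered SNP columns."""

    names: list[str]
    sequences: list[str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences must share one length")

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


def _code_genotype(ref: str, alt: str, a: int, b: int) -> str:
    if a < 0:
        return "N"
    alleles = {ref if a == 0 else alt, ref if b == 0 else alt}
    if len(alleles) == 1:
        return alleles.pop()
    return _IUPAC[frozenset(alleles)]


def snp_alignment_rows(table: VariantTable):
    """Yield (sample, sequence) pairs one at a time (memory: one row)."""
    refs = [str(r).upper() for r in table.ref]
    alts = []
    for i, site_alts in enumerate(table.alts):
        if len(site_alts) != 1:
            raise ValueError(f"site {i}: SNP alignment requires biallelic sites")
        if len(refs[i]) != 1 or len(site_alts[0]) != 1:
            raise ValueError(f"site {i}: alleles must be single bases")
        alts.append(str(site_alts[0]).upper())
    for j, sample in enumerate(table.samples):
        gt = table.genotypes[:, j, :]
        seq = "".join(
            _code_genotype(refs[i], alts[i], int(gt[i, 0]), int(gt[i, 1]))
            for i in range(table.n_sites)
        )
        yield sample, seq


def snp_alignment(table: VariantTable) -> SnpAlignment:
    """Materialised SNP supermatrix: hom ref -> ref base, hom alt -> alt base,
    het -> IUPAC ambiguity, missing -> N."""
    names, seqs = [], []
    for name, seq in snp_alignment_rows(table):
        names.append(name)
        seqs.append(seq)
    return SnpAlignment(names, seqs)


def write_phylip(aln, path) -> None:
    """Write relaxed PHYLIP: ``n_samples n_sites`` header, then
    ``name<space>sequence`` rows.

    ``aln`` is a :class:`SnpAlignment` or an iterable of (name, seq) pairs
    plus a known count — for streaming use :func:`write_phylip_stream`.
    """
    write_phylip_stream(zip(aln.names, aln.sequences), len(aln.names), aln.n_sites, path)


def write_phylip_stream(rows, n_samples: int, n_sites: int, path) -> None:
    seen: set[str] = set()
    with open(path, "w") as fh:
        fh.write(f"{n_samples} {n_sites}\n")
        for name, seq in rows:
            if any(ch.isspace() for ch in name):
                raise ValueError(f"sample name {name!r} contains whitespace")
            if name in seen:
                raise ValueError(f"duplicate sample name {name!r}")
            seen.add(name)
            fh.write(f"{name} {seq}\n")


def write_fasta(aln: SnpAlignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(aln.names, aln.sequences):
            fh.write(f">{name}\n{seq}\n")


def allele_sharing_distance(dosage: np.ndarray) -> np.ndarray:
    """Pairwise allele-sharing distance of a (n_samples, n_sites) dosage
    matrix: mean over sites called in both samples of |d_i - d_j| / 2.

    A pair with no shared called site gets NaN (neighbor joining refuses).
    """
    x = np.asarray(dosage, dtype=np.float64)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    d = np.zeros((n, n))
    called = ~np.isnan(x)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            m = int(both.sum())
            d[i, j] = d[j, i] = (
                float(np.abs(x[i, both] - x[j, both]).mean() / 2.0) if m else np.nan
            )
    return d


def nj_tree(distance: np.ndarray, labels: list[str]) -> str:
    """Saitou-Nei neighbor joining; returns a newick string.

    Ties in the Q criterion break deterministically toward the smallest
    (i, j) in taxon order.  Negative branch lengths are clamped to zero with
    the deficit transferred to the sibling branch, preserving the pair's
    path length.
    """
    d = np.array(distance, dtype=np.float64)
    n = d.shape[0]
    if n != d.shape[1] or n < 3:
        raise ValueError("need a square matrix over >= 3 taxa")
    if np.isnan(d).any():
        raise ValueError("distance matrix has missing entries")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    nodes: list[str] = list(labels)
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)  # first minimum: row-major
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        li = 0.5 * sub[ai, aj] + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = sub[ai, aj] - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        # distances of the new node to the remaining taxa
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.vstack([d, dnew[None, :]])
        dnew2 = np.append(dnew, 0.0)
        d = np.hstack([d, dnew2[:, None]])
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    i, j = active
    half = d[i, j] / 2.0
    return f"({nodes[i]}:{half:.10g},{nodes[j]}:{half:.10g});"


def collapse_low_support(newick: str, threshold: float = 0.7) -> str:
    """Contract internal edges with support below ``threshold``.

    Support values are read from internal-node labels of the newick string
    (the convention of the usual ML/coalescent tree builders).  The leaf set
    is unchanged; each collapsed edge merges its child's children into the
    parent, producing a polytomy.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable newick: {exc}") from exc
    to_collapse = []
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        if node.label is None:
            continue
        if float(node.label) < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def count_polytomies(newick: str) -> int:
    """Count multifurcations: internal nodes of degree > 3.

    The seed node of a newick string has no parent edge, so the usual basal
    trifurcation of an unrooted tree (three children at the root) is *not*
    counted; a root with four or more children is.
    """
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )
    count = 0
    for nd in tree.preorder_internal_node_iter():
        limit = 3 if nd.parent_node is None else 2
        if len(nd.child_nodes()) > limit:
            count += 1
    return count
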