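"""Hard-filter cascade for joint-genotyped SNP tables.

Stage order is fixed and matches standard practice for transcriptome-derived
cohorts: (1) site-level hard filters on the caller annotations, (2) genotype
masking by per-sample depth, (3) the biallelic / missingness / MAF site
filters.  Each stage's in/removed/surviving counts are recorded in a
:class:`FilterReport` so survivor numbers are auditable per stage.

Conventions (all documented because the thresholds sit on open boundaries):

* A site is removed by the hard filters iff any *present* annotation violates
  its threshold (``QD < 10 OR FS > 60 OR MQ < 40 OR SOR > 3 OR
  MQRankSum < -12.5 OR ReadPosRankSum < -8``); missing annotations never
  cause removal.
* Depth masking compares each genotype's DP against a mean depth with strict
  inequalities: masked iff ``DP < mean/3`` or ``DP > 2*mean``; boundary
  values are kept.  The reference mean is, by default, the site's mean DP
  across samples (``depth_reference="site"``): that statistic depends only on
  the site's own depths, so the mask — and with it the whole cascade — is
  exactly idempotent.  The alternative ``depth_reference="sample"`` uses each
  sample's mean DP over its called genotypes; it treats depth as a per-sample
  sequencing property but is *not* idempotent under re-application, because
  removing sites or masking genotypes shifts the per-sample means.
* Missingness is strict (``< 0.10``); MAF uses ``>= 0.02`` by default to
  match the conventional ``--maf`` semantics of the vcftools family, with a
  strict mode available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sweepscan.core_io import ANNOTATION_KEYS, MISSING, VariantTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    qd_min: float = 10.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    sor_max: float = 3.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    depth_low_factor: float = 1.0 / 3.0
    depth_high_factor: float = 2.0
    depth_reference: str = "site"  # "site" (idempotent) or "sample"
    max_missing: float = 0.10
    maf_min: float = 0.02
    maf_strict: bool = False  # True: MAF must exceed maf_min strictly

    def __post_init__(self):
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must lie in [0,1]")
        if not 0.0 <= self.maf_min <= 1.0:
            raise ValueError("maf_min must lie in [0,1]")
        if self.depth_low_factor <= 0 or self.depth_high_factor <= 0:
            raise ValueError("depth factors must be positive")
        if self.depth_reference not in ("site", "sample"):
            raise ValueError("depth_reference must be 'site' or 'sample'")


@dataclass
class FilterReport:
    """Per-stage bookkeeping: surviving(stage k) == in(stage k+1)."""

    stages: list[str] = field(default_factory=list)
    sites_in: list[int] = field(default_factory=list)
    sites_removed: list[int] = field(default_factory=list)
    sites_surviving: list[int] = field(default_factory=list)
    genotypes_masked: int = 0

    def add(self, stage: str, n_in: int, n_removed: int) -> None:
        self.stages.append(stage)
        self.sites_in.append(n_in)
        self.sites_removed.append(n_removed)
        self.sites_surviving.append(n_in - n_removed)

    def extend(self, other: "FilterReport") -> None:
        self.stages += other.stages
        self.sites_in += other.sites_in
        self.sites_removed += other.sites_removed
        self.sites_surviving += other.sites_surviving
        self.genotypes_masked += other.genotypes_masked

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.stages,
                "sites_in": self.sites_in,
                "sites_removed": self.sites_removed,
                "sites_surviving": self.sites_surviving,
            }
        )


def _violations(table: VariantTable, t: FilterThresholds) -> np.ndarray:
    """Boolean (S,) array: any present annotation violates its threshold."""

    def bad(key, op, thr):
        a = table.annotations[key]
        with np.errstate(invalid="ignore"):
            return ~np.isnan(a) & op(a, thr)

    lt, gt = np.less, np.greater
    fail = bad("QD", lt, t.qd_min)
    fail |= bad("FS", gt, t.fs_max)
    fail |= bad("MQ", lt, t.mq_min)
    fail |= bad("SOR", gt, t.sor_max)
    fail |= bad("MQRankSum", lt, t.mqranksum_min)
    fail |= bad("ReadPosRankSum", lt, t.readposranksum_min)
    return fail


def apply_hard_filters(
    table: VariantTable, t: FilterThresholds = FilterThresholds()
) -> tuple[VariantTable, FilterReport]:
    """Remove sites whose present annotations violate the hard thresholds."""
    fail = _violations(table, t)
    report = FilterReport()
    report.add("hard_filter", table.n_sites, int(fail.sum()))
    return table.take(~fail), report


def mask_by_depth(
    table: VariantTable, t: FilterThresholds = FilterThresholds()
) -> tuple[VariantTable, int]:
    """Mask genotypes whose DP is outside (mean/3, 2*mean), strict bounds.

    With ``depth_reference="site"`` (default) the mean is the site's average
    DP over genotypes with a recorded depth — a per-site statistic that never
    changes when genotypes are masked or other sites removed, so the mask is
    idempotent.  With ``depth_reference="sample"`` it is each sample's
    average DP over its *called* genotypes.  A site (or sample) with no
    usable depths has no defined mean; its genotypes are left untouched and
    a warning is logged.
    """
    gt = table.genotypes.copy()
    dp = table.depths
    called = (gt >= 0).all(axis=2)  # (S, N)
    has_dp = dp != MISSING
    if t.depth_reference == "site":
        n_usable = has_dp.sum(axis=1)  # per site
        with np.errstate(invalid="ignore"):
            sums = np.where(has_dp, dp, 0).sum(axis=1, dtype=np.float64)
            means = np.where(n_usable > 0, sums / np.maximum(n_usable, 1), np.nan)
        n_undefined = int((n_usable == 0).sum())
        if n_undefined:
            logger.warning(
                "%d sites have no recorded depths; depth mask skipped there",
                n_undefined,
            )
        lo = (means * t.depth_low_factor)[:, None]
        hi = (means * t.depth_high_factor)[:, None]
    else:
        usable = called & has_dp
        n_usable = usable.sum(axis=0)  # per sample
        with np.errstate(invalid="ignore"):
            sums = np.where(usable, dp, 0).sum(axis=0, dtype=np.float64)
            means = np.where(n_usable > 0, sums / np.maximum(n_usable, 1), np.nan)
        for j in np.flatnonzero(n_usable == 0):
            logger.warning(
                "sample %s has no called genotypes with depth; depth mask skipped",
                table.samples[j],
            )
        lo = (means * t.depth_low_factor)[None, :]
        hi = (means * t.depth_high_factor)[None, :]
    with np.errstate(invalid="ignore"):
        out_of_band = called & has_dp & ((dp < lo) | (dp > hi))
    masked_total = int(out_of_band.sum())
    gt[out_of_band] = MISSING
    out = table.take(np.arange(table.n_sites))
    out.genotypes = gt
    return out, masked_total


def _observed_alt_info(table: VariantTable):
    """Per site: number of distinct observed alt alleles, missing fraction,
    minor allele frequency over called alleles, and the single observed alt
    index (or -1)."""
    gt = table.genotypes
    s, n, _ = gt.shape
    called_gt = (gt >= 0).all(axis=2)
    # computed as missing/n (not 1 - called/n) so boundary fractions like
    # 1/10 == 0.1 compare exactly against the strict threshold
    miss_frac = (n - called_gt.sum(axis=1)) / n

    n_obs_alt = np.zeros(s, dtype=np.int32)
    single_alt = np.full(s, -1, dtype=np.int32)
    maf = np.zeros(s, dtype=np.float64)
    for i in range(s):
        alleles = gt[i][called_gt[i]].ravel()
        if alleles.size == 0:
            continue
        counts = np.bincount(alleles, minlength=1)
        alt_present = np.flatnonzero(counts[1:] > 0) + 1
        n_obs_alt[i] = len(alt_present)
        if len(alt_present) == 1:
            single_alt[i] = alt_present[0]
            ac = counts[alt_present[0]]
            f = ac / alleles.size
            maf[i] = min(f, 1.0 - f)
    return n_obs_alt, miss_frac, maf, single_alt


def filter_biallelic_missing_maf(
    table: VariantTable, t: FilterThresholds = FilterThresholds()
) -> tuple[VariantTable, FilterReport]:
    """Keep sites with exactly one observed alt allele, missing fraction
    strictly below ``max_missing`` and MAF at least ``maf_min`` (strictly
    above it in strict mode), all over called genotypes.

    Surviving sites are recoded so the observed alt is allele index 1.
    """
    n_obs_alt, miss_frac, maf, single_alt = _observed_alt_info(table)
    report = FilterReport()

    bi = n_obs_alt == 1
    report.add("biallelic", table.n_sites, int((~bi).sum()))

    ok_miss = bi & (miss_frac < t.max_missing)
    report.add("missingness", int(bi.sum()), int((bi & ~(miss_frac < t.max_missing)).sum()))

    if t.maf_strict:
        ok_maf = ok_miss & (maf > t.maf_min)
    else:
        ok_maf = ok_miss & (maf >= t.maf_min)
    report.add("maf", int(ok_miss.sum()), int(ok_miss.sum()) - int(ok_maf.sum()))

    out = table.take(ok_maf)
    # recode: observed alt becomes allele 1, alts trimmed to that allele
    kept = np.flatnonzero(ok_maf)
    for row, i in enumerate(kept):
        a = int(single_alt[i])
        if a != 1 or len(out.alts[row]) != 1:
            out.alts[row] = (out.alts[row][a - 1],)
            gt = out.genotypes[row]
            gt[gt == a] = 1
    return out, report


def apply_filter_cascade(
    table: VariantTable, t: FilterThresholds = FilterThresholds()
) -> tuple[VariantTable, FilterReport]:
    """Full cascade: hard filters -> depth mask -> biallelic/missing/MAF."""
    out, report = apply_hard_filters(table, t)
    out, masked = mask_by_depth(out, t)
    report.genotypes_masked = masked
    out, rep2 = filter_biallelic_missing_maf(out, t)
    report.extend(rep2)
    return out, report


@dataclass
class DensityResult:
    windows: pd.DataFrame  # contig, start, end, n_snps, per_mb, flagged
    per_contig: pd.DataFrame  # contig, length, n_snps, per_mb, bp_per_variant
    genome_per_mb: float


def snp_density(
    table: VariantTable,
    window_bp: int = 1_000_000,
    flag_per_mb: float = 200.0,
) -> DensityResult:
    """Non-overlapping windowed SNP counts and per-Mb densities.

    Requires every contig's length (from the VCF header or config); windows
    whose density exceeds ``flag_per_mb`` are flagged, mirroring how dense
    SNP regions are highlighted in genome-wide density plots.
    """
    rows = []
    contig_rows = []
    total_len = 0
    for ci, contig in enumerate(table.contigs):
        length = table.contig_lengths.get(contig)
        if length is None:
            raise ValueError(f"unknown length for contig {contig!r}")
        total_len += length
        positions = table.pos[table.contig_idx == ci]
        n_windows = math.ceil(length / window_bp)
        counts = np.bincount((positions - 1) // window_bp, minlength=n_windows)
        for w in range(n_windows):
            start = w * window_bp + 1
            end = min((w + 1) * window_bp, length)
            span = end - start + 1
            per_mb = counts[w] / span * 1e6
            rows.append((contig, start, end, int(counts[w]), per_mb, per_mb > flag_per_mb))
        n_snps = len(positions)
        contig_rows.append(
            (
                contig,
                length,
                n_snps,
                n_snps / length * 1e6,
                length / n_snps if n_snps else np.nan,
            )
        )
    windows = pd.DataFrame(
        rows, columns=["contig", "start", "end", "n_snps", "per_mb", "flagged"]
    )
    per_contig = pd.DataFrame(
        contig_rows, columns=["contig", "length", "n_snps", "per_mb", "bp_per_variant"]
    )
    genome_per_mb = table.n_sites / total_len * 1e6 if total_len else 0.0
    return DensityResult(windows, per_contig, genome_per_mb)
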