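"""Cross-population composite-likelihood-ratio (XP-CLR style) sweep scan.

The test contrasts two models of allele-frequency differentiation between an
*object* population (scanned for sweeps) and a *reference* population:

Neutral model
    The object-population frequency ``p`` drifted from the reference
    frequency ``p_ref`` by Brownian motion: ``p ~ Normal(p_ref,
    omega * p_ref * (1 - p_ref))`` truncated to (0, 1), with the truncated
    tail mass absorbed as point masses at 0 and 1 (fixation / loss).  The
    drift scale ``omega`` is estimated from genome-wide data by the method
    of moments.  The observed alt count ``k`` out of ``n`` sampled alleles
    is Binomial(n, p), integrated over the drift law.

Sweep model
    A site at distance ``d`` from a selected locus escapes the sweep with
    probability ``c = 1 - exp(-kappa * d)``.  With probability ``c`` the
    site follows the neutral law; otherwise the allele either rode the
    swept haplotype (probability ``p_ref``) and its frequency maps to
    ``1 - c + c*p``, or it did not (probability ``1 - p_ref``) and maps to
    ``c*p``, with ``p`` drawn from the neutral drift law.

For each sliding window the composite log-likelihood sums per-site log
likelihoods, down-weighted for linkage disequilibrium (a SNP's weight is the
reciprocal of the number of window SNPs whose genotype-dosage r^2 with it
reaches ``ld_r2_max``, itself included), and the scan statistic is

    clr = max(0, 2 * (max_kappa L1(kappa) - L0))

maximised over a log-spaced kappa grid.  Both directions (each population in
turn as object) are scanned independently.

Numerical notes: the drift integral uses Gauss-Legendre quadrature over the
+-8 sigma support of the truncated normal (exact-enough for the smooth
binomial integrand; the missing tail mass is < 1e-15); reference frequencies
fixed at 0 or 1 are epsilon-shrunk to ``(count + 0.5) / (n + 1)`` so the
drift variance stays positive; likelihoods are floored at 1e-300 before the
log.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr, xlog1py, xlogy

from sweepscan.core_io import PopulationAssignment, VariantTable

logger = logging.getLogger(__name__)

_LIK_FLOOR = 1e-300
_SIGMA_TINY = 1e-8  # below this the drift law degenerates to a point mass
_SUPPORT_SD = 8.0


def default_kappa_grid(n_points: int = 12, lo: float = 1e-7, hi: float = 1e-3) -> np.ndarray:
    return np.logspace(math.log10(lo), math.log10(hi), n_points)


@dataclass
class XpclrParams:
    """Scan parameters; defaults follow the standard command-line usage
    (200-kb windows stepped by 20 kb, LD pruning at r^2 0.95, at most 600
    SNPs per window, top 1% of positive blocks called per direction)."""

    window_size: int = 200_000
    step: int = 20_000
    ld_r2_max: float = 0.95
    max_snps: int = 600
    kappa_grid: np.ndarray = field(default_factory=default_kappa_grid)
    omega: float | None = None  # estimated from data when None
    freq_grid_size: int = 64
    top_fraction: float = 0.01

    def __post_init__(self):
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")
        if not 0.0 < self.ld_r2_max <= 1.0:
            raise ValueError("ld_r2_max must lie in (0,1]")
        if len(self.kappa_grid) == 0 or self.freq_grid_size < 2:
            raise ValueError("grids must be non-empty")


# ---------------------------------------------------------------------------
# drift-law quadrature


class _DriftGrids:
    """Per-site quadrature of the truncated-normal drift law.

    For each site: Gauss-Legendre nodes ``p`` over the +-8 sigma support
    intersected with (0,1), node masses ``w`` (quadrature weight times the
    normal density), and boundary atoms ``m0``/``m1`` carrying the tail mass
    below 0 / above 1.
    """

    def __init__(self, k, n, p_ref, omega: float, grid_size: int):
        self.k = np.asarray(k, dtype=np.float64)
        self.n = np.asarray(n, dtype=np.float64)
        self.p_ref = np.asarray(p_ref, dtype=np.float64)
        self.logC = (
            gammaln(self.n + 1) - gammaln(self.k + 1) - gammaln(self.n - self.k + 1)
        )
        sigma = np.sqrt(omega * self.p_ref * (1.0 - self.p_ref))
        self.sigma = sigma
        self.degenerate = sigma < _SIGMA_TINY
        sig = np.where(self.degenerate, 1.0, sigma)  # placeholder, unused rows
        lo = np.maximum(0.0, self.p_ref - _SUPPORT_SD * sig)
        hi = np.minimum(1.0, self.p_ref + _SUPPORT_SD * sig)
        x, wq = np.polynomial.legendre.leggauss(grid_size)
        mid = (lo + hi)[:, None] / 2.0
        half = (hi - lo)[:, None] / 2.0
        self.p = mid + half * x[None, :]  # (m, G)
        z = (self.p - self.p_ref[:, None]) / sig[:, None]
        dens = np.exp(-0.5 * z * z) / (sig[:, None] * math.sqrt(2.0 * math.pi))
        self.w = half * wq[None, :] * dens  # (m, G) node masses
        self.m0 = ndtr(-self.p_ref / sig)
        self.m1 = ndtr((self.p_ref - 1.0) / sig)

    def neutral_lik(self) -> np.ndarray:
        """Per-site neutral likelihood P(k | n, p_ref, omega)."""
        k = self.k[:, None]
        n = self.n[:, None]
        pmf = np.exp(self.logC[:, None] + xlogy(k, self.p) + xlog1py(n - k, -self.p))
        lik = (self.w * pmf).sum(axis=1)
        lik = lik + self.m0 * (self.k == 0) + self.m1 * (self.k == self.n)
        if self.degenerate.any():
            idx = self.degenerate
            lik[idx] = np.exp(
                self.logC[idx]
                + xlogy(self.k[idx], self.p_ref[idx])
                + xlog1py(self.n[idx] - self.k[idx], -self.p_ref[idx])
            )
        return lik

    def sweep_lik(self, c: np.ndarray, neutral: np.ndarray) -> np.ndarray:
        """Per-site sweep likelihood for escape probabilities ``c``.

        ``c`` has shape (..., m); returns the same shape.  ``neutral`` is the
        output of :meth:`neutral_lik`.
        """
        c = np.asarray(c, dtype=np.float64)
        k = self.k[..., :, None]
        n = self.n[..., :, None]
        logC = self.logC[..., :, None]
        cc = c[..., :, None]
        q1 = 1.0 - cc + cc * self.p  # allele rode the swept haplotype
        q2 = cc * self.p
        pmf1 = np.exp(logC + xlogy(k, q1) + xlog1py(n - k, -q1))
        pmf2 = np.exp(logC + xlogy(k, q2) + xlog1py(n - k, -q2))
        t1 = (self.w * pmf1).sum(axis=-1)
        t2 = (self.w * pmf2).sum(axis=-1)
        # boundary atoms: p = 0 maps to 1-c (branch 1) / 0 (branch 2),
        # p = 1 maps to 1 (branch 1) / c (branch 2)
        q0 = 1.0 - c
        t1 = t1 + self.m0 * np.exp(self.logC + xlogy(self.k, q0) + xlog1py(self.n - self.k, -q0))
        t1 = t1 + self.m1 * (self.k == self.n)
        t2 = t2 + self.m0 * (self.k == 0)
        t2 = t2 + self.m1 * np.exp(self.logC + xlogy(self.k, c) + xlog1py(self.n - self.k, -c))
        lik = c * neutral + (1.0 - c) * (self.p_ref * t1 + (1.0 - self.p_ref) * t2)
        if self.degenerate.any():
            # point-mass drift law: p == p_ref exactly
            idx = self.degenerate
            pr = self.p_ref[idx]
            ci = c[..., idx]
            q1d = 1.0 - ci + ci * pr
            q2d = ci * pr
            t1d = np.exp(self.logC[idx] + xlogy(self.k[idx], q1d) + xlog1py(self.n[idx] - self.k[idx], -q1d))
            t2d = np.exp(self.logC[idx] + xlogy(self.k[idx], q2d) + xlog1py(self.n[idx] - self.k[idx], -q2d))
            lik[..., idx] = ci * neutral[idx] + (1.0 - ci) * (pr * t1d + (1.0 - pr) * t2d)
        return lik


def _log_binom(k: float, n: float, q: float) -> float:
    logC = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(logC + xlogy(k, q) + xlog1py(n - k, -q))


def _logconcave_quad(logf, dlogf, grid_size: int) -> float:
    """log of the integral over (0,1) of a log-concave integrand.

    Finds the unique interior mode by bisection on the (strictly decreasing)
    derivative, brackets the region where the integrand is within e^-60 of
    its peak, and Gauss-Legendre-integrates with the peak factored out, so
    the result is accurate at any magnitude.
    """
    eps = 1e-14
    lo, hi = eps, 1.0 - eps
    if dlogf(lo) <= 0:
        mode = lo
    elif dlogf(hi) >= 0:
        mode = hi
    else:
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if dlogf(mid) > 0:
                lo = mid
            else:
                hi = mid
        mode = (lo + hi) / 2.0
    # window edges: where logf falls `drop` nats below the mode (bisection on
    # each monotone flank); mass outside is < e^-drop relative to the total
    drop = 60.0
    peak = logf(mode)
    target = peak - drop

    def _edge(inner: float, outer: float) -> float:
        if logf(outer) >= target:
            return outer
        a, b = inner, outer  # logf(a) >= target > logf(b)
        for _ in range(80):
            mid = (a + b) / 2.0
            if logf(mid) >= target:
                a = mid
            else:
                b = mid
        return b

    a = _edge(mode, 0.0)
    b = _edge(mode, 1.0)
    x, wq = np.polynomial.legendre.leggauss(grid_size)
    p = (a + b) / 2.0 + (b - a) / 2.0 * x
    w = (b - a) / 2.0 * wq
    logs = np.array([logf(float(v)) for v in p])
    peak = logs.max()
    if not np.isfinite(peak):
        return -np.inf
    return float(peak + np.log(np.sum(w * np.exp(logs - peak))))


def _log_integral_affine(
    k: int, n: int, p_ref: float, sigma: float, a0: float, a1: float, grid_size: int
) -> float:
    """log of integral_0^1 Binom(k | n, a0 + a1 p) Normal(p; p_ref, sigma) dp.

    ``a0 + a1 p`` must map (0,1) into [0,1].  Handles the degenerate slope
    ``a1 == 0`` (constant success probability) in closed form.
    """
    logC = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    log_norm_const = -math.log(sigma) - 0.5 * math.log(2.0 * math.pi)
    interior_mass_log = None
    if a1 == 0.0:
        # Binom factor constant; integral = pmf * interior normal mass
        z0, z1 = (0.0 - p_ref) / sigma, (1.0 - p_ref) / sigma
        mass = float(ndtr(z1) - ndtr(z0))
        return _log_binom(k, n, a0) + (math.log(mass) if mass > 0 else -np.inf)

    def logf(p: float) -> float:
        q = a0 + a1 * p
        q = min(max(q, 0.0), 1.0)
        z = (p - p_ref) / sigma
        return (
            float(logC + xlogy(k, q) + xlog1py(n - k, -q))
            + log_norm_const
            - 0.5 * z * z
        )

    def dlogf(p: float) -> float:
        q = a0 + a1 * p
        term = 0.0
        if k > 0:
            term += k * a1 / q if q > 0 else math.copysign(np.inf, a1)
        if k < n:
            term -= (n - k) * a1 / (1.0 - q) if q < 1 else math.copysign(np.inf, a1)
        return term - (p - p_ref) / sigma**2

    return _logconcave_quad(logf, dlogf, grid_size)


def _logsumexp_terms(terms: list[float]) -> float:
    finite = [t for t in terms if t > -np.inf]
    if not finite:
        return -np.inf
    m = max(finite)
    return m + math.log(sum(math.exp(t - m) for t in finite))


def neutral_site_loglik(
    k: int, n: int, p_ref: float, omega: float, freq_grid_size: int = 64
) -> float:
    """Log P(k | n) under the neutral drift law (see module docstring).

    Exact mode-centered quadrature of the log-concave integrand, accurate
    even when the observed frequency sits deep in the drift law's tail.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < p_ref < 1.0:
        raise ValueError("p_ref must lie strictly in (0,1)")
    sigma = math.sqrt(omega * p_ref * (1.0 - p_ref))
    if sigma < _SIGMA_TINY:
        return _log_binom(k, n, p_ref)
    terms = [_log_integral_affine(k, n, p_ref, sigma, 0.0, 1.0, freq_grid_size)]
    m0 = float(ndtr(-p_ref / sigma))
    m1 = float(ndtr((p_ref - 1.0) / sigma))
    if k == 0 and m0 > 0:
        terms.append(math.log(m0))
    if k == n and m1 > 0:
        terms.append(math.log(m1))
    return _logsumexp_terms(terms)


def sweep_site_loglik(
    k: int, n: int, p_ref: float, omega: float, c: float, freq_grid_size: int = 64
) -> float:
    """Log P(k | n) under the sweep mixture with escape probability ``c``.

    With probability ``c`` the neutral law applies; otherwise the drift
    frequency ``p`` maps to ``1 - c + c p`` (probability ``p_ref``) or
    ``c p`` (probability ``1 - p_ref``).  At ``c == 1`` this reduces to the
    neutral model exactly.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("escape probability c must lie in [0,1]")
    neutral = neutral_site_loglik(k, n, p_ref, omega, freq_grid_size)
    if c == 1.0:
        return neutral
    sigma = math.sqrt(omega * p_ref * (1.0 - p_ref))
    if sigma < _SIGMA_TINY:
        t1 = _log_binom(k, n, 1.0 - c + c * p_ref)
        t2 = _log_binom(k, n, c * p_ref)
    else:
        m0 = float(ndtr(-p_ref / sigma))
        m1 = float(ndtr((p_ref - 1.0) / sigma))
        t1_terms = [_log_integral_affine(k, n, p_ref, sigma, 1.0 - c, c, freq_grid_size)]
        if m0 > 0:
            t1_terms.append(math.log(m0) + _log_binom(k, n, 1.0 - c))
        if k == n and m1 > 0:
            t1_terms.append(math.log(m1))
        t1 = _logsumexp_terms(t1_terms)
        t2_terms = [_log_integral_affine(k, n, p_ref, sigma, 0.0, c, freq_grid_size)]
        if k == 0 and m0 > 0:
            t2_terms.append(math.log(m0))
        if m1 > 0:
            t2_terms.append(math.log(m1) + _log_binom(k, n, c))
        t2 = _logsumexp_terms(t2_terms)
    parts = []
    if c > 0:
        parts.append(math.log(c) + neutral)
    if p_ref > 0:
        parts.append(math.log1p(-c) + math.log(p_ref) + t1)
    if p_ref < 1:
        parts.append(math.log1p(-c) + math.log1p(-p_ref) + t2)
    return _logsumexp_terms(parts)


# ---------------------------------------------------------------------------
# data preparation


def _pop_allele_counts(table: VariantTable, cols: np.ndarray):
    """(alt count, called allele count) per site for the given columns."""
    sub = table.genotypes[:, cols, :]
    called = (sub >= 0).all(axis=2)
    n = 2 * called.sum(axis=1)
    k = np.where(called, sub.sum(axis=2), 0).sum(axis=1)
    return k.astype(np.int64), n.astype(np.int64)


def _shrunk_ref_freq(k_ref: np.ndarray, n_ref: np.ndarray) -> np.ndarray:
    """Reference frequency with boundary shrinkage (count+0.5)/(n+1) applied
    only at fixation/loss so the drift variance stays positive."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_ref > 0, k_ref / np.maximum(n_ref, 1), np.nan)
    boundary = (p == 0.0) | (p == 1.0)
    p = np.where(boundary, (k_ref + 0.5) / (n_ref + 1.0), p)
    return p


def estimate_omega(
    table: VariantTable,
    pops: PopulationAssignment,
    min_sites: int = 500,
    informative_band: tuple[float, float] = (0.05, 0.95),
) -> float:
    """Method-of-moments drift scale between object and reference.

    Over biallelic sites with raw reference frequency strictly inside
    ``informative_band``, averages ``[(p_obj - p_ref)^2 -
    p_ref(1-p_ref)/n_obj_alleles] / [p_ref(1-p_ref)]`` — the subtraction
    removes the binomial sampling noise of the object sample — and floors the
    result at 1e-6.
    """
    i_obj = pops.indices(table.samples, pops.obj_label)
    i_ref = pops.indices(table.samples, pops.ref_label)
    k_o, n_o = _pop_allele_counts(table, i_obj)
    k_r, n_r = _pop_allele_counts(table, i_ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_r = np.where(n_r > 0, k_r / np.maximum(n_r, 1), np.nan)
        p_o = np.where(n_o > 0, k_o / np.maximum(n_o, 1), np.nan)
    lo, hi = informative_band
    ok = (
        table.biallelic_mask()
        & (n_o > 0)
        & (n_r > 0)
        & (p_r > lo)
        & (p_r < hi)
    )
    if int(ok.sum()) < min_sites:
        raise ValueError(
            f"only {int(ok.sum())} informative sites (< {min_sites}); "
            "supply a fixed omega via XpclrParams(omega=...)"
        )
    v = p_r[ok] * (1.0 - p_r[ok])
    num = (p_o[ok] - p_r[ok]) ** 2 - v / n_o[ok]
    return float(max(np.mean(num / v), 1e-6))


def ld_weights(dosages: np.ndarray, r2_max: float) -> np.ndarray:
    """Reciprocal-count LD down-weighting of window SNPs.

    ``dosages`` is (n_snps, n_samples) with NaN for missing; missing entries
    are mean-imputed per SNP.  A SNP's weight is ``1 / #{j': r^2 >= r2_max}``
    with itself included; zero-variance SNPs correlate 0 with everything.
    """
    d = np.array(dosages, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] < 1:
        raise ValueError("dosages must be a (n_snps, n_samples) matrix")
    row_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=1)
    row_mean = np.where(np.isnan(row_mean), 0.0, row_mean)
    miss = np.isnan(d)
    d[miss] = np.take(row_mean, np.nonzero(miss)[0])
    d -= d.mean(axis=1, keepdims=True)
    norms = np.sqrt((d * d).sum(axis=1))
    zero = norms == 0
    norms[zero] = 1.0
    z = d / norms[:, None]
    r2 = (z @ z.T) ** 2
    r2[zero, :] = 0.0
    r2[:, zero] = 0.0
    np.fill_diagonal(r2, 1.0)  # self always counted, also for zero-variance
    counts = (r2 >= r2_max).sum(axis=1)
    return 1.0 / counts


def contig_window_count(length: int, window_size: int, step: int) -> int:
    """Windows starting at 1, stepping by ``step``, fully inside the contig."""
    if length < window_size:
        return 0
    return (length - window_size) // step + 1


def xpclr_scan(
    table: VariantTable,
    pops: PopulationAssignment,
    params: XpclrParams = None,
    directions: str = "both",
) -> pd.DataFrame:
    """Sliding-window composite-likelihood sweep scan.

    Returns one row per (window, direction) with columns contig, start, end,
    focal, n_snps, clr, kappa_hat, direction.  Windows with zero usable SNPs
    are omitted.  ``directions`` is "both", "obj" or "ref" (which population
    is scanned as the object).
    """
    if params is None:
        params = XpclrParams()
    dir_list = {
        "both": [pops, pops.swapped()],
        "obj": [pops],
        "ref": [pops.swapped()],
    }[directions]

    rows = []
    for assign in dir_list:
        rows.extend(_scan_one_direction(table, assign, params))
    return pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "focal", "n_snps", "clr", "kappa_hat", "direction"],
    )


def _scan_one_direction(table: VariantTable, pops: PopulationAssignment, params: XpclrParams):
    i_obj = pops.indices(table.samples, pops.obj_label)
    i_ref = pops.indices(table.samples, pops.ref_label)
    k_o, n_o = _pop_allele_counts(table, i_obj)
    k_r, n_r = _pop_allele_counts(table, i_ref)
    usable = table.biallelic_mask() & (n_o > 0) & (n_r > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info(
            "direction %s: %d sites unusable (non-biallelic or uncalled)",
            pops.obj_label,
            n_dropped,
        )
    idx = np.flatnonzero(usable)
    p_ref = _shrunk_ref_freq(k_r[idx], n_r[idx])
    omega = params.omega if params.omega is not None else estimate_omega(table, pops)

    grids = _DriftGrids(k_o[idx], n_o[idx], p_ref, omega, params.freq_grid_size)
    neutral = grids.neutral_lik()
    log_neutral = np.log(np.maximum(neutral, _LIK_FLOOR))

    # dosage rows for LD weighting, object population only
    sub = table.genotypes[idx][:, i_obj, :]
    called = (sub >= 0).all(axis=2)
    dosages = np.where(called, sub.sum(axis=2), -1).astype(np.float64)
    dosages[dosages < 0] = np.nan

    kappas = np.asarray(params.kappa_grid, dtype=np.float64)
    pos = table.pos[idx]
    contig_of = table.contig_idx[idx]

    out = []
    for ci, contig in enumerate(table.contigs):
        length = table.contig_lengths.get(contig)
        if length is None:
            raise ValueError(f"unknown length for contig {contig!r}")
        local = np.flatnonzero(contig_of == ci)
        local_pos = pos[local]
        nwin = contig_window_count(length, params.window_size, params.step)
        for w in range(nwin):
            start = 1 + w * params.step
            end = start + params.window_size - 1
            focal = (start + end) / 2.0
            lo = np.searchsorted(local_pos, start, side="left")
            hi = np.searchsorted(local_pos, end, side="right")
            sel = local[lo:hi]
            if sel.size == 0:
                continue
            d = np.abs(pos[sel] - focal)
            if sel.size > params.max_snps:
                keep = np.argsort(d, kind="stable")[: params.max_snps]
                keep.sort()
                sel = sel[keep]
                d = np.abs(pos[sel] - focal)
            w_ld = ld_weights(dosages[sel], params.ld_r2_max)

            c = -np.expm1(-kappas[:, None] * d[None, :])  # (K, m)
            site_grids = _subset_grids(grids, sel)
            lik1 = site_grids.sweep_lik(c, neutral[sel])
            log_l1 = np.log(np.maximum(lik1, _LIK_FLOOR))
            l1 = (w_ld[None, :] * log_l1).sum(axis=1)
            l0 = float((w_ld * log_neutral[sel]).sum())
            best = int(np.argmax(l1))
            clr = max(0.0, 2.0 * (float(l1[best]) - l0))
            out.append(
                (
                    contig,
                    start,
                    end,
                    focal,
                    int(sel.size),
                    clr,
                    float(kappas[best]),
                    pops.obj_label,
                )
            )
    return out


def _subset_grids(grids: _DriftGrids, sel: np.ndarray) -> _DriftGrids:
    sub = object.__new__(_DriftGrids)
    sub.k = grids.k[sel]
    sub.n = grids.n[sel]
    sub.p_ref = grids.p_ref[sel]
    sub.logC = grids.logC[sel]
    sub.sigma = grids.sigma[sel]
    sub.degenerate = grids.degenerate[sel]
    sub.p = grids.p[sel]
    sub.w = grids.w[sel]
    sub.m0 = grids.m0[sel]
    sub.m1 = grids.m1[sel]
    return sub


def top_percent_blocks(
    blocks: pd.DataFrame,
    fraction: float = 0.01,
    positive_only: bool = True,
    contigs: list[str] | None = None,
) -> pd.DataFrame:
    """Per-direction top blocks by clr: restrict to clr > 0 (when
    ``positive_only``), take the ceil(fraction * N) highest per direction with
    deterministic tie-breaking (clr desc, contig order, start)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0,1)")
    if contigs is None:
        contigs = list(dict.fromkeys(blocks["contig"]))
    order = {ct: i for i, ct in enumerate(contigs)}
    picked = []
    for direction, grp in blocks.groupby("direction", sort=True):
        if positive_only:
            grp = grp[grp["clr"] > 0]
        if grp.empty:
            logger.warning("no positive blocks in direction %s", direction)
            continue
        grp = grp.copy()
        grp["_co"] = grp["contig"].map(order)
        grp = grp.sort_values(
            ["clr", "_co", "start"], ascending=[False, True, True], kind="mergesort"
        )
        k = math.ceil(fraction * len(grp))
        picked.append(grp.head(k).drop(columns="_co"))
    if not picked:
        return blocks.iloc[0:0]
    return pd.concat(picked, ignore_index=True)
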