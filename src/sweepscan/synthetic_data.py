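"""Seeded synthetic two-population cohorts with implanted selective sweeps.

The generator emulates the statistical structure of a joint-genotyped
transcriptome cohort of two diverged populations:

* Ancestral allele frequencies ``p0`` are drawn from a configurable law
  (default Uniform(0.05, 0.95)); each population's present-day frequency is a
  Balding-Nichols draw, ``Beta(p0(1-F)/F, (1-p0)(1-F)/F)``, whose mean is
  ``p0`` and variance ``F * p0 * (1-p0)``.  This matches the mean/variance
  drift structure the composite-likelihood sweep scan assumes, at O(1) cost
  per site.
* Selective sweeps are implanted by the hitchhiking approximation: a site at
  distance ``d`` from the swept locus escapes the sweep with probability
  ``c = 1 - exp(-kappa * d)``; a non-escaping allele is dragged to frequency
  ``1 - c + c*p`` if it rode the swept haplotype (probability ``p``) and to
  ``c*p`` otherwise.  The transform acts on population frequencies, not
  haplotypes, so linkage among swept sites is induced only through the shared
  frequency distortion.
* Genotypes are Binomial(2, p) per diploid sample; depths are negative
  binomial; each hard-filter annotation is drawn from a passing band and
  replaced by a value from a failing band with its configured fraction, so a
  controllable share of sites fails each filter.

Everything is driven by a single integer seed; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sweepscan.core_io import (
    ANNOTATION_KEYS,
    MISSING,
    GeneModel,
    PopulationAssignment,
    VariantTable,
    write_gene_models,
    write_population_file,
    write_vcf,
)

# Bands for the six tracked annotations: (passing low, passing high),
# (failing low, failing high).  Failing bands sit strictly beyond each
# threshold so boundary behaviour is exercised with hand-built records only.
_PASS_BANDS = {
    "QD": (15.0, 35.0),
    "FS": (0.0, 30.0),
    "MQ": (50.0, 60.0),
    "SOR": (0.5, 2.5),
    "MQRankSum": (-3.0, 3.0),
    "ReadPosRankSum": (-3.0, 3.0),
}
_FAIL_BANDS = {
    "QD": (0.0, 9.9),
    "FS": (60.1, 120.0),
    "MQ": (0.0, 39.9),
    "SOR": (3.1, 6.0),
    "MQRankSum": (-20.0, -12.6),
    "ReadPosRankSum": (-12.0, -8.1),
}


@dataclass(frozen=True)
class SweepRegion:
    """An implanted sweep: center position, per-bp escape-rate scale, target."""

    center: int
    kappa: float
    population: str  # "obj" or "ref"

    @property
    def half_width(self) -> float:
        """Span where hitchhiking dominates escape (c <= 1/2)."""
        return math.log(2.0) / self.kappa


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the study design the scan targets: a 97-sample object
    population against a 3-sample reference, drifted from a shared ancestral
    frequency; depths negative binomial with mean 30 and dispersion 5.
    """

    n_obj: int = 97
    n_ref: int = 3
    n_sites: int = 5000
    contig_length: int = 2_000_000
    contig_name: str = "chr1"
    F_obj: float = 0.1
    F_ref: float = 0.1
    sweep_regions: list[SweepRegion] = field(default_factory=list)
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    filter_fail_fractions: dict[str, float] = field(default_factory=dict)
    triallelic_fraction: float = 0.0
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    missing_rate: float = 0.0
    gene_length: int = 2000
    gene_spacing: int = 5000
    obj_label: str = "CSS"
    ref_label: str = "CSA"
    seed: int = 0

    def __post_init__(self):
        for name, f in (("F_obj", self.F_obj), ("F_ref", self.F_ref)):
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {f}")
        if self.n_sites > self.contig_length:
            raise ValueError("n_sites exceeds contig_length")
        for k, frac in self.filter_fail_fractions.items():
            if k not in ANNOTATION_KEYS:
                raise ValueError(f"unknown filter annotation {k!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fail fraction for {k} outside [0,1]")
        for r in self.sweep_regions:
            if not 0 < r.center <= self.contig_length:
                raise ValueError("sweep center outside contig")
            if r.kappa <= 0:
                raise ValueError("sweep kappa must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort, for parameter-recovery tests."""

    sites: pd.DataFrame  # pos, p0, p_obj, p_ref, sweep_flag, fail_<KEY>...
    genes: pd.DataFrame  # gene_id, sweep_overlap

    def to_tsv(self, sites_path, genes_path) -> None:
        self.sites.to_csv(sites_path, sep="\t", index=False)
        self.genes.to_csv(genes_path, sep="\t", index=False)


def draw_population_freqs(p0, F: float, rng: np.random.Generator):
    """Balding-Nichols draw: Beta(p0(1-F)/F, (1-p0)(1-F)/F) per element.

    Expectation ``p0``, variance ``F * p0 * (1 - p0)``.
    """
    if not 0.0 < F < 1.0:
        raise ValueError(f"drift parameter F must lie in (0,1), got {F}")
    p0 = np.asarray(p0, dtype=np.float64)
    scale = (1.0 - F) / F
    return rng.beta(p0 * scale, (1.0 - p0) * scale)


def apply_sweep_transform(p, distance_bp, kappa: float, rng: np.random.Generator):
    """Hitchhiking transform of population frequency at a linked site.

    With escape probability ``c = 1 - exp(-kappa * distance_bp)`` the site is
    untouched; otherwise the alt allele either rode the swept haplotype
    (probability ``p``) and lands at ``1 - c + c*p``, or did not and lands at
    ``c*p``.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    p = np.asarray(p, dtype=np.float64)
    d = np.asarray(distance_bp, dtype=np.float64)
    c = -np.expm1(-kappa * d)
    escaped = rng.random(p.shape) < c
    rode = rng.random(p.shape) < p
    swept = np.where(rode, 1.0 - c + c * p, c * p)
    return np.where(escaped, p, swept)


def _simulate_arrays(config: SimulationConfig, rng: np.random.Generator):
    s = config.n_sites
    pos = np.sort(rng.choice(config.contig_length, size=s, replace=False)) + 1

    lo, hi = config.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=s)
    p_obj = draw_population_freqs(p0, config.F_obj, rng)
    p_ref = draw_population_freqs(p0, config.F_ref, rng)

    sweep_flag = np.zeros(s, dtype=bool)
    for region in config.sweep_regions:
        d = np.abs(pos - region.center).astype(np.float64)
        target = p_obj if region.population == "obj" else p_ref
        transformed = apply_sweep_transform(target, d, region.kappa, rng)
        if region.population == "obj":
            p_obj = transformed
        else:
            p_ref = transformed
        sweep_flag |= d <= region.half_width
    return pos, p0, p_obj, p_ref, sweep_flag


def _draw_genotypes(p, n_ind, missing_rate, rng):
    """(S, n_ind, 2) allele pairs from Binomial(2, p) dosages."""
    s = len(p)
    dos = rng.binomial(2, p[:, None], size=(s, n_ind)).astype(np.int8)
    gt = np.empty((s, n_ind, 2), dtype=np.int8)
    gt[:, :, 0] = (dos >= 1).astype(np.int8)  # het stored as 0/1
    gt[:, :, 1] = (dos == 2).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random((s, n_ind)) < missing_rate
        gt[miss] = MISSING
    return gt


_BASES = np.array(list("ACGT"))


def simulate_cohort(
    config: SimulationConfig, out_dir=None
) -> tuple[VariantTable, list[GeneModel], PopulationAssignment, SyntheticTruth]:
    """Generate one seeded cohort; optionally write VCF/BED/TSV files.

    Returns the in-memory table, tiled gene models, the population assignment
    and the ground-truth record.  With ``out_dir`` set, writes ``cohort.vcf``,
    ``genes.bed``, ``populations.tsv``, ``truth_sites.tsv`` and
    ``truth_genes.tsv`` under it.
    """
    rng = np.random.default_rng(config.seed)
    s = config.n_sites
    pos, p0, p_obj, p_ref, sweep_flag = _simulate_arrays(config, rng)

    gt_obj = _draw_genotypes(p_obj, config.n_obj, config.missing_rate, rng)
    gt_ref = _draw_genotypes(p_ref, config.n_ref, config.missing_rate, rng)
    genotypes = np.concatenate([gt_obj, gt_ref], axis=1)
    n = config.n_obj + config.n_ref

    # ref/alt bases; a configurable fraction of sites gets a second alt allele
    # carried by one extra heterozygous genotype (retained until the biallelic
    # filter stage).
    ref_idx = rng.integers(0, 4, size=s)
    alt_off = rng.integers(1, 4, size=s)
    alt_idx = (ref_idx + alt_off) % 4
    refs = _BASES[ref_idx].astype(object)
    alts: list[tuple[str, ...]] = [(str(_BASES[alt_idx[i]]),) for i in range(s)]
    triallelic = rng.random(s) < config.triallelic_fraction
    for i in np.flatnonzero(triallelic):
        third = (ref_idx[i] + (alt_off[i] % 3) + 1) % 4
        if third in (ref_idx[i], alt_idx[i]):
            third = ({0, 1, 2, 3} - {int(ref_idx[i]), int(alt_idx[i])}).pop()
        alts[i] = alts[i] + (str(_BASES[third]),)
        j = int(rng.integers(0, n))
        genotypes[i, j] = (0, 2)

    # depths: negative binomial with mean depth_mean, dispersion r
    r = config.depth_dispersion
    nb_p = r / (r + config.depth_mean)
    depths = rng.negative_binomial(r, nb_p, size=(s, n)).astype(np.int32)

    annotations: dict[str, np.ndarray] = {}
    fail_labels: dict[str, np.ndarray] = {}
    for key in ANNOTATION_KEYS:
        lo, hi = _PASS_BANDS[key]
        vals = rng.uniform(lo, hi, size=s)
        frac = config.filter_fail_fractions.get(key, 0.0)
        fails = rng.random(s) < frac
        flo, fhi = _FAIL_BANDS[key]
        vals[fails] = rng.uniform(flo, fhi, size=int(fails.sum()))
        # quantize to 3 decimals and cast through float32 so the textual VCF
        # representation (htslib prints INFO floats with 6 significant
        # digits) round-trips bit-exactly; every band is < 1000 in magnitude
        # and sits >= 0.1 away from its threshold, so quantization can never
        # move a value across a filter boundary
        annotations[key] = np.round(vals, 3).astype(np.float32).astype(np.float64)
        fail_labels[key] = fails

    table = VariantTable(
        contigs=[config.contig_name],
        contig_lengths={config.contig_name: config.contig_length},
        samples=[f"obj{i:03d}" for i in range(config.n_obj)]
        + [f"ref{i:03d}" for i in range(config.n_ref)],
        contig_idx=np.zeros(s, dtype=np.int32),
        pos=pos.astype(np.int64),
        ref=refs,
        alts=alts,
        annotations=annotations,
        genotypes=genotypes,
        depths=depths,
    )

    genes: list[GeneModel] = []
    start = 1
    gi = 0
    while start + config.gene_length - 1 <= config.contig_length:
        genes.append(
            GeneModel(f"g{gi:05d}", config.contig_name, start, start + config.gene_length - 1, "+")
        )
        gi += 1
        start += config.gene_spacing

    labels = {name: (config.obj_label if name.startswith("obj") else config.ref_label)
              for name in table.samples}
    pops = PopulationAssignment(labels, config.obj_label, config.ref_label)

    truth_sites = pd.DataFrame(
        {
            "contig": config.contig_name,
            "pos": pos,
            "p0": p0,
            "p_obj": p_obj,
            "p_ref": p_ref,
            "sweep_flag": sweep_flag,
            "triallelic": triallelic,
            **{f"fail_{k}": fail_labels[k] for k in ANNOTATION_KEYS},
        }
    )
    gene_overlap = []
    for g in genes:
        hit = any(
            g.start <= reg.center + reg.half_width and g.end >= reg.center - reg.half_width
            for reg in config.sweep_regions
        )
        gene_overlap.append(hit)
    truth_genes = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "sweep_overlap": gene_overlap}
    )
    truth = SyntheticTruth(truth_sites, truth_genes)

    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_vcf(table, os.path.join(out_dir, "cohort.vcf"))
        write_gene_models(genes, os.path.join(out_dir, "genes.bed"))
        write_population_file(pops, os.path.join(out_dir, "populations.tsv"))
        truth.to_tsv(
            os.path.join(out_dir, "truth_sites.tsv"),
            os.path.join(out_dir, "truth_genes.tsv"),
        )
    return table, genes, pops, truth
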