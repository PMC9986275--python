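"""End-to-end pipeline: one config in, a manifest of stage artifacts out.

The stage order mirrors the analysis flow the package implements: filter ->
SNP density -> windowed pi -> per-site Fst -> XP-CLR scan -> two-method
sweep intersection -> enrichment -> PCA -> PHYLIP export -> NJ tree.  Every
stage writes its artifact under the output directory and registers it in a
JSON manifest with a sha256 hash, so re-running an identical config and seed
reproduces identical hashes for all stages.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from sweepscan import core_io, popgen_stats, structure_phylo, sweep_genes, variant_filtering, xpclr_scan
from sweepscan.synthetic_data import SimulationConfig, SweepRegion, simulate_cohort

logger = logging.getLogger(__name__)

_TOP_KEYS = {
    "seed",
    "output_dir",
    "simulate",
    "inputs",
    "filters",
    "pi_window",
    "xpclr",
    "fst_gene_threshold",
    "fst_top_fraction",
    "xpclr_top_genes",
    "pca_components",
    "collapse_support",
    "log_level",
}


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 0
    simulate: SimulationConfig | None = None
    vcf: str | None = None
    bed: str | None = None
    pops: str | None = None
    obj_label: str = "CSS"
    ref_label: str = "CSA"
    terms: str | None = None
    thresholds: variant_filtering.FilterThresholds = field(
        default_factory=variant_filtering.FilterThresholds
    )
    pi_window: int = 20_000
    xpclr_params: xpclr_scan.XpclrParams = field(default_factory=xpclr_scan.XpclrParams)
    fst_gene_threshold: float = 0.9
    fst_top_fraction: float = 0.10
    xpclr_top_genes: int = 500
    pca_components: int = 10

    def __post_init__(self):
        if (self.simulate is None) == (self.vcf is None):
            raise ValueError("config needs exactly one of a simulate block or input paths")


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    for key in mapping:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            extra = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ValueError(f"unknown config key {key!r} in {where}{extra}")


def validate_config(path) -> PipelineConfig:
    """Load a YAML config file, fill defaults, reject unknown keys.

    Relative paths resolve against the config file's directory.
    """
    base = os.path.dirname(os.path.abspath(path))
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _reject_unknown(raw, _TOP_KEYS, "top level")
    if "simulate" in raw and "inputs" in raw:
        raise ValueError("config must not contain both 'simulate' and 'inputs'")

    def resolve(p):
        return p if p is None or os.path.isabs(p) else os.path.join(base, p)

    seed = int(raw.get("seed", 0))
    kwargs: dict = {
        "output_dir": resolve(raw.get("output_dir", "sweepscan_out")),
        "seed": seed,
    }
    if "simulate" in raw:
        sim = dict(raw["simulate"] or {})
        sweeps = [SweepRegion(**s) for s in sim.pop("sweep_regions", [])]
        allowed = set(SimulationConfig.__dataclass_fields__) - {"sweep_regions"}
        _reject_unknown(sim, allowed, "simulate")
        sim.setdefault("seed", seed)
        kwargs["simulate"] = SimulationConfig(sweep_regions=sweeps, **sim)
        kwargs["obj_label"] = kwargs["simulate"].obj_label
        kwargs["ref_label"] = kwargs["simulate"].ref_label
    else:
        inputs = dict(raw.get("inputs") or {})
        _reject_unknown(
            inputs, {"vcf", "bed", "pops", "obj_label", "ref_label", "terms"}, "inputs"
        )
        for k in ("vcf", "bed", "pops", "terms"):
            if k in inputs:
                kwargs[k] = resolve(inputs[k])
        for k in ("obj_label", "ref_label"):
            if k in inputs:
                kwargs[k] = inputs[k]
    if "filters" in raw:
        filt = dict(raw["filters"] or {})
        _reject_unknown(filt, set(variant_filtering.FilterThresholds.__dataclass_fields__), "filters")
        kwargs["thresholds"] = variant_filtering.FilterThresholds(**filt)
    if "xpclr" in raw:
        xp = dict(raw["xpclr"] or {})
        _reject_unknown(xp, set(xpclr_scan.XpclrParams.__dataclass_fields__), "xpclr")
        if "kappa_grid" in xp:
            xp["kappa_grid"] = np.asarray(xp["kappa_grid"], dtype=float)
        kwargs["xpclr_params"] = xpclr_scan.XpclrParams(**xp)
    for k in ("pi_window", "xpclr_top_genes", "pca_components"):
        if k in raw:
            kwargs[k] = int(raw[k])
    for k in ("fst_gene_threshold", "fst_top_fraction"):
        if k in raw:
            kwargs[k] = float(raw[k])
    config = PipelineConfig(**kwargs)
    logger.info("resolved config: %s", config)
    return config


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: str, seed: int):
        self.out_dir = out_dir
        self.data = {"seed": seed, "stages": []}

    def add(self, stage: str, params: dict, outputs: list[str], **counts):
        self.data["stages"].append(
            {
                "stage": stage,
                "parameters": params,
                "outputs": {
                    os.path.relpath(p, self.out_dir): _sha256(p) for p in outputs
                },
                **counts,
            }
        )

    def write(self) -> str:
        path = os.path.join(self.out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def _synthetic_term_map(genes: list[core_io.GeneModel], seed: int, n_terms: int = 20):
    """Deterministic gene->term assignment for simulate-mode enrichment."""
    rng = np.random.default_rng(seed + 1)
    term_map: dict[str, set[str]] = {f"T{i:04d}": set() for i in range(n_terms)}
    for g in genes:
        for t in rng.choice(n_terms, size=rng.integers(1, 4), replace=False):
            term_map[f"T{int(t):04d}"].add(g.gene_id)
    return {t: gs for t, gs in term_map.items() if gs}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to
    ``manifest.json`` under the output directory)."""
    os.makedirs(config.output_dir, exist_ok=True)
    out = lambda name: os.path.join(config.output_dir, name)
    manifest = _Manifest(config.output_dir, config.seed)

    # stage 0: inputs (simulated or read)
    if config.simulate is not None:
        table, genes, pops, truth = simulate_cohort(config.simulate, out_dir=out("input"))
        term_map = _synthetic_term_map(genes, config.seed)
        manifest.add(
            "simulate",
            {"config": str(config.simulate)},
            [out("input/cohort.vcf"), out("input/genes.bed"), out("input/populations.tsv"),
             out("input/truth_sites.tsv"), out("input/truth_genes.tsv")],
            n_sites=table.n_sites,
            n_samples=table.n_samples,
        )
    else:
        table = core_io.read_vcf(config.vcf)
        genes = core_io.read_gene_models(config.bed) if config.bed else []
        pops = core_io.read_population_file(config.pops, config.obj_label, config.ref_label)
        pops.check_samples(table.samples)
        term_map = sweep_genes.read_term_map(config.terms) if config.terms else {}
        manifest.add(
            "load",
            {"vcf": config.vcf, "bed": config.bed, "pops": config.pops},
            [],
            n_sites=table.n_sites,
            n_samples=table.n_samples,
        )

    # stage 1: filter cascade
    filtered, report = variant_filtering.apply_filter_cascade(table, config.thresholds)
    core_io.write_vcf(filtered, out("filtered.vcf"))
    report.to_frame().to_csv(out("filter_report.tsv"), sep="\t", index=False)
    manifest.add(
        "filter",
        {"thresholds": str(config.thresholds)},
        [out("filtered.vcf"), out("filter_report.tsv")],
        genotypes_masked=report.genotypes_masked,
        sites_surviving=filtered.n_sites,
    )

    # stage 2: SNP density
    density = variant_filtering.snp_density(filtered)
    density.windows.to_csv(out("snp_density.tsv"), sep="\t", index=False)
    manifest.add(
        "density",
        {"window_bp": 1_000_000},
        [out("snp_density.tsv")],
        genome_per_mb=density.genome_per_mb,
    )

    # stage 3: windowed pi per population
    pi_rows = []
    for label in (pops.obj_label, pops.ref_label):
        for w in popgen_stats.windowed_pi(filtered, pops, label, config.pi_window):
            pi_rows.append((label, w.contig, w.start, w.end, w.n_variant_sites, w.pi))
    pd.DataFrame(
        pi_rows, columns=["population", "contig", "start", "end", "n_variant_sites", "pi"]
    ).to_csv(out("windowed_pi.tsv"), sep="\t", index=False)
    manifest.add("pi", {"window_bp": config.pi_window}, [out("windowed_pi.tsv")])

    # stage 4: per-site Fst, z-transform, gene scores, top fraction
    fst = popgen_stats.fst_table(filtered, pops)
    fst["z"] = popgen_stats.z_transform_fst(fst["theta"].to_numpy())
    fst.to_csv(out("fst_sites.tsv"), sep="\t", index=False)
    gene_scores = popgen_stats.gene_fst(fst, genes, contigs=filtered.contigs)
    gene_scores.to_csv(out("fst_genes.tsv"), sep="\t", index=False)
    fst_top = popgen_stats.top_fraction(gene_scores, config.fst_top_fraction, contigs=filtered.contigs)
    fst_top.to_csv(out("fst_top_genes.tsv"), sep="\t", index=False)
    manifest.add(
        "fst",
        {"top_fraction": config.fst_top_fraction},
        [out("fst_sites.tsv"), out("fst_genes.tsv"), out("fst_top_genes.tsv")],
        n_sites=len(fst),
        n_top_genes=len(fst_top),
    )

    # stage 5: XP-CLR scan + top blocks
    blocks = xpclr_scan.xpclr_scan(filtered, pops, config.xpclr_params)
    blocks.to_csv(out("xpclr_blocks.tsv"), sep="\t", index=False)
    top_blocks = xpclr_scan.top_percent_blocks(
        blocks, config.xpclr_params.top_fraction, contigs=filtered.contigs
    )
    top_blocks.to_csv(out("xpclr_top_blocks.tsv"), sep="\t", index=False)
    manifest.add(
        "xpclr",
        {
            "window_size": config.xpclr_params.window_size,
            "step": config.xpclr_params.step,
            "ld_r2_max": config.xpclr_params.ld_r2_max,
            "max_snps": config.xpclr_params.max_snps,
            "top_fraction": config.xpclr_params.top_fraction,
        },
        [out("xpclr_blocks.tsv"), out("xpclr_top_blocks.tsv")],
        n_blocks=len(blocks),
        n_top_blocks=len(top_blocks),
    )

    # stage 6: two-method intersection
    xp_genes = sweep_genes.xpclr_gene_table(blocks, genes)
    intersection = sweep_genes.intersect_sweeps(
        gene_scores, xp_genes, config.fst_gene_threshold, config.xpclr_top_genes
    )
    intersection.genes.to_csv(out("sweep_genes.tsv"), sep="\t", index=False)
    manifest.add(
        "intersection",
        {
            "fst_threshold": config.fst_gene_threshold,
            "xpclr_top_n": config.xpclr_top_genes,
            "provenance": intersection.provenance,
        },
        [out("sweep_genes.tsv")],
        n_genes=len(intersection.genes),
    )

    # stage 7: enrichment of the intersection set
    background = {g.gene_id for g in genes}
    selected = intersection.gene_ids & background
    enrich = sweep_genes.hypergeom_enrich(selected, background, term_map) if term_map else pd.DataFrame(
        columns=["term_id", "term_name", "k", "K", "n", "N", "p", "q"]
    )
    enrich.to_csv(out("enrichment.tsv"), sep="\t", index=False)
    manifest.add(
        "enrichment",
        {"n_terms": len(term_map)},
        [out("enrichment.tsv")],
        n_selected=len(selected),
    )

    # stage 8: PCA
    dosage = filtered.dosage().T  # samples x sites
    pca = structure_phylo.genotype_pca(dosage, filtered.samples, k=config.pca_components)
    pca_df = pd.DataFrame(
        pca.coordinates, columns=[f"PC{i+1}" for i in range(pca.coordinates.shape[1])]
    )
    pca_df.insert(0, "sample", pca.samples)
    pca_df.to_csv(out("pca.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {"component": [f"PC{i+1}" for i in range(len(pca.explained))], "explained": pca.explained}
    ).to_csv(out("pca_variance.tsv"), sep="\t", index=False)
    manifest.add(
        "pca", {"k": config.pca_components}, [out("pca.tsv"), out("pca_variance.tsv")]
    )

    # stage 9: PHYLIP export
    structure_phylo.write_phylip_stream(
        structure_phylo.snp_alignment_rows(filtered),
        filtered.n_samples,
        filtered.n_sites,
        out("snps.phy"),
    )
    manifest.add("phylip", {}, [out("snps.phy")], n_sites=filtered.n_sites)

    # stage 10: NJ tree on allele-sharing distances
    dist = structure_phylo.allele_sharing_distance(dosage)
    newick = structure_phylo.nj_tree(dist, filtered.samples)
    with open(out("nj_tree.nwk"), "w") as fh:
        fh.write(newick + "\n")
    manifest.add("nj_tree", {"distance": "allele_sharing"}, [out("nj_tree.nwk")])

    manifest.write()
    return manifest.data
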