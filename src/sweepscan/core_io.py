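"""Shared data model and readers/writers for VCF, BED and population files.

The central object is :class:`VariantTable`, an array-backed container holding
one joint-genotyped cohort: per-site coordinates and annotations, and per
sample genotype allele pairs plus read depths.  Coordinates are 1-based
inclusive everywhere inside the package (VCF convention); BED intervals are
converted on read.  Phase separators are accepted and discarded — every
downstream statistic is allele-frequency based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

#: INFO keys tracked as per-site annotations, in canonical order.
ANNOTATION_KEYS = ("QD", "FS", "MQ", "SOR", "MQRankSum", "ReadPosRankSum")

MISSING = -1  # sentinel for missing genotype alleles and depths


class VcfParseError(ValueError):
    """Malformed VCF content (bad header, non-monotone positions, ...)."""


class FormatError(ValueError):
    """Malformed BED / population-file content."""


@dataclass(frozen=True)
class SiteAnnotations:
    """The six hard-filter annotations of one site; ``nan`` marks absence."""

    QD: float = np.nan
    FS: float = np.nan
    MQ: float = np.nan
    SOR: float = np.nan
    MQRankSum: float = np.nan
    ReadPosRankSum: float = np.nan


@dataclass(frozen=True)
class VariantSite:
    """A read-only per-site view into a :class:`VariantTable`."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    annotations: SiteAnnotations
    genotypes: np.ndarray  # (n_samples, 2) int8, MISSING == -1
    depths: np.ndarray  # (n_samples,) int32, MISSING == -1

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


@dataclass
class VariantTable:
    """Genotype matrix plus per-site annotations and per-genotype depths.

    Attributes
    ----------
    contigs : list of str
        Contig names in header order (not lexically sorted).
    contig_lengths : dict
        Contig name -> length in bp; entries may be absent if the source
        header carried no lengths.
    samples : list of str
    contig_idx : (S,) int32 array of indices into ``contigs``.
    pos : (S,) int64 array of 1-based positions.
    ref : (S,) str array.
    alts : list of tuples of alternate alleles per site.
    annotations : dict mapping each of :data:`ANNOTATION_KEYS` to a (S,)
        float64 array with ``nan`` for absent keys.
    genotypes : (S, N, 2) int8 array of allele indices, -1 for missing;
        a half-missing call is stored as fully missing.
    depths : (S, N) int32 array of per-genotype DP, -1 for missing.
    """

    contigs: list[str]
    contig_lengths: dict[str, int]
    samples: list[str]
    contig_idx: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alts: list[tuple[str, ...]]
    annotations: dict[str, np.ndarray] = field(repr=False)
    genotypes: np.ndarray = field(repr=False)
    depths: np.ndarray = field(repr=False)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site(self, i: int) -> VariantSite:
        ann = SiteAnnotations(**{k: float(self.annotations[k][i]) for k in ANNOTATION_KEYS})
        return VariantSite(
            contig=self.contigs[self.contig_idx[i]],
            pos=int(self.pos[i]),
            ref=str(self.ref[i]),
            alts=tuple(self.alts[i]),
            annotations=ann,
            genotypes=self.genotypes[i],
            depths=self.depths[i],
        )

    def take(self, index) -> "VariantTable":
        """Subset sites by boolean mask or integer index, preserving order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            contig_idx=self.contig_idx[index].copy(),
            pos=self.pos[index].copy(),
            ref=self.ref[index].copy(),
            alts=[self.alts[i] for i in index],
            annotations={k: v[index].copy() for k, v in self.annotations.items()},
            genotypes=self.genotypes[index].copy(),
            depths=self.depths[index].copy(),
        )

    def biallelic_mask(self) -> np.ndarray:
        return np.fromiter((len(a) == 1 for a in self.alts), dtype=bool, count=self.n_sites)

    def dosage(self) -> np.ndarray:
        """(S, N) alt-allele dosage for biallelic sites; nan where missing.

        Requires every site to be biallelic (allele indices in {0, 1}).
        """
        if not bool(self.biallelic_mask().all()):
            raise ValueError("dosage() requires a biallelic-only table")
        gt = self.genotypes
        called = (gt >= 0).all(axis=2)
        dos = gt.sum(axis=2, dtype=np.float64)
        dos[~called] = np.nan
        return dos

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on breach."""
        s, n = self.n_sites, self.n_samples
        if self.genotypes.shape != (s, n, 2) or self.depths.shape != (s, n):
            raise ValueError("genotype/depth array shapes inconsistent with table")
        order = np.lexsort((self.pos, self.contig_idx))
        if not np.array_equal(order, np.arange(s)):
            raise ValueError("sites not sorted by (contig order, position)")
        for i, alts in enumerate(self.alts):
            if str(self.ref[i]) in alts:
                raise ValueError(f"site {i}: ref allele repeated among alts")
            if int(self.genotypes[i].max(initial=-1)) > len(alts):
                raise ValueError(f"site {i}: genotype allele index out of range")


def _header_for(table: VariantTable) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name in table.contigs:
        length = table.contig_lengths.get(name)
        if length is None:
            header.contigs.add(name)
        else:
            header.contigs.add(name, length=length)
    for key in ANNOTATION_KEYS:
        header.info.add(key, 1, "Float", f"{key} site annotation")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in table.samples:
        header.add_sample(s)
    return header


def read_vcf(path) -> VariantTable:
    """Read a VCF v4.x file (GT + DP FORMAT fields) into a :class:`VariantTable`.

    Record order is preserved; absent INFO keys become missing annotations,
    multiallelic records are retained.  Non-monotone positions within a contig
    raise :class:`VcfParseError` naming the offending line.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        contigs = list(vf.header.contigs)
        contig_lengths = {
            name: c.length for name, c in vf.header.contigs.items() if c.length
        }
        n_header_lines = str(vf.header).count("\n")

        contig_order = {name: i for i, name in enumerate(contigs)}
        contig_idx, pos, ref, alts_list = [], [], [], []
        ann_cols: dict[str, list[float]] = {k: [] for k in ANNOTATION_KEYS}
        gts, dps = [], []
        last_pos: dict[str, int] = {}
        for line_no, rec in enumerate(vf, start=n_header_lines + 1):
            if rec.chrom not in contig_order:
                # contig absent from header: append in order of appearance
                contig_order[rec.chrom] = len(contigs)
                contigs.append(rec.chrom)
            if rec.pos < last_pos.get(rec.chrom, 0):
                raise VcfParseError(
                    f"line {line_no}: position {rec.pos} on {rec.chrom} is below "
                    f"the previous record ({last_pos[rec.chrom]})"
                )
            last_pos[rec.chrom] = rec.pos
            contig_idx.append(contig_order[rec.chrom])
            pos.append(rec.pos)
            ref.append(rec.ref)
            alts_list.append(tuple(rec.alts or ()))
            for k in ANNOTATION_KEYS:
                v = rec.info.get(k)
                ann_cols[k].append(np.nan if v is None else float(v))
            site_gt = np.full((len(samples), 2), MISSING, dtype=np.int8)
            site_dp = np.full(len(samples), MISSING, dtype=np.int32)
            for j, s in enumerate(samples):
                call = rec.samples[j]
                alleles = call.get("GT")
                if alleles is not None and len(alleles) == 2 and None not in alleles:
                    site_gt[j] = alleles
                dp = call.get("DP")
                if dp is not None:
                    site_dp[j] = dp
            gts.append(site_gt)
            dps.append(site_dp)

    s = len(pos)
    table = VariantTable(
        contigs=contigs,
        contig_lengths=contig_lengths,
        samples=samples,
        contig_idx=np.asarray(contig_idx, dtype=np.int32),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alts=alts_list,
        annotations={k: np.asarray(v, dtype=np.float64) for k, v in ann_cols.items()},
        genotypes=(
            np.stack(gts) if s else np.empty((0, len(samples), 2), dtype=np.int8)
        ),
        depths=np.stack(dps) if s else np.empty((0, len(samples)), dtype=np.int32),
    )
    return table


def write_vcf(table: VariantTable, path) -> None:
    """Write ``table`` as uncompressed VCF; lossless round-trip with
    :func:`read_vcf` for positions, alleles, GT, DP and the six annotations.

    Missing annotations are omitted from INFO (never written as 0); fully
    missing genotypes appear as ``./.``.
    """
    header = _header_for(table)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(table.n_sites):
            rec = out.new_record(
                contig=table.contigs[table.contig_idx[i]],
                start=int(table.pos[i]) - 1,
                alleles=(str(table.ref[i]),) + tuple(table.alts[i]),
            )
            for k in ANNOTATION_KEYS:
                v = table.annotations[k][i]
                if not np.isnan(v):
                    rec.info[k] = float(v)
            for j in range(table.n_samples):
                a, b = table.genotypes[i, j]
                rec.samples[j]["GT"] = None if a == MISSING else (int(a), int(b))
                dp = table.depths[i, j]
                if dp != MISSING:
                    rec.samples[j]["DP"] = int(dp)
            out.write(rec)


@dataclass(frozen=True)
class GeneModel:
    """One gene interval, stored 1-based inclusive after BED conversion."""

    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "?"


def read_gene_models(path) -> list[GeneModel]:
    """Read BED (0-based half-open, >=4 columns) into 1-based GeneModels.

    A BED line ``chr1 999 2000 g1`` covers 1-based positions 1000..2000.
    Duplicate gene ids and empty intervals are rejected.
    """
    models: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise FormatError(f"line {line_no}: BED needs >=4 columns")
            contig, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise FormatError(f"line {line_no}: empty interval {start}>={end}")
            if name in seen:
                raise FormatError(f"line {line_no}: duplicate gene id {name!r}")
            seen.add(name)
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "?"
            models.append(GeneModel(name, contig, start + 1, end, strand))
    return models


def write_gene_models(models: list[GeneModel], path) -> None:
    """Write gene models back to BED4(+strand)."""
    with open(path, "w") as fh:
        for g in models:
            fh.write(f"{g.contig}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand if g.strand in '+-' else '.'}\n")


@dataclass(frozen=True)
class PopulationAssignment:
    """Sample -> population labels with designated scan populations.

    ``obj_label`` is the population scanned for sweeps (e.g. the large CSS
    cultivar panel), ``ref_label`` the reference (e.g. the 3-sample CSA set).
    """

    labels: dict[str, str]
    obj_label: str
    ref_label: str

    def __post_init__(self):
        if self.obj_label == self.ref_label:
            raise FormatError("object and reference labels must differ")
        for lab in (self.obj_label, self.ref_label):
            if lab not in self.labels.values():
                raise FormatError(f"population {lab!r} has no samples")

    def members(self, label: str) -> list[str]:
        return [s for s, l in self.labels.items() if l == label]

    def indices(self, samples: list[str], label: str) -> np.ndarray:
        """Column indices of ``label``'s members in a sample list."""
        self.check_samples(samples)
        want = {s for s, l in self.labels.items() if l == label}
        return np.asarray([i for i, s in enumerate(samples) if s in want], dtype=np.intp)

    def check_samples(self, samples: list[str]) -> None:
        missing = [s for s in samples if s not in self.labels]
        if missing:
            raise FormatError(
                "samples without population label: " + ", ".join(missing[:10])
            )

    def swapped(self) -> "PopulationAssignment":
        return PopulationAssignment(self.labels, self.ref_label, self.obj_label)


def read_population_file(path, obj_label: str, ref_label: str) -> PopulationAssignment:
    """Read a two-column TSV ``sample<TAB>population`` file.

    Duplicate sample rows with conflicting labels are rejected; validation
    against a cohort's sample list happens on first use
    (:meth:`PopulationAssignment.check_samples`).
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise FormatError(f"line {line_no}: expected two columns")
            sample, label = parts
            if labels.get(sample, label) != label:
                raise FormatError(f"line {line_no}: conflicting label for {sample!r}")
            labels[sample] = label
    return PopulationAssignment(labels, obj_label, ref_label)


def write_population_file(assignment: PopulationAssignment, path) -> None:
    with open(path, "w") as fh:
        for sample, label in assignment.labels.items():
            fh.write(f"{sample}\t{label}\n")
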