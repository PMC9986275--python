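"""Shared fixtures and helpers for the sweepscan test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sweepscan.core_io import ANNOTATION_KEYS, PopulationAssignment, VariantTable

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_table(
    pos,
    genotypes,
    contig: str = "chr1",
    contig_length: int | None = None,
    refs=None,
    alts=None,
    annotations: dict | None = None,
    depths=None,
    samples: list[str] | None = None,
) -> VariantTable:
    """Build a single-contig VariantTable from arrays, filling defaults."""
    pos = np.asarray(pos, dtype=np.int64)
    genotypes = np.asarray(genotypes, dtype=np.int8)
    s, n, _ = genotypes.shape
    assert len(pos) == s
    if contig_length is None:
        contig_length = int(pos.max(initial=0)) + 1000
    if refs is None:
        refs = np.asarray(["A"] * s, dtype=object)
    else:
        refs = np.asarray(refs, dtype=object)
    if alts is None:
        alts = [("G",)] * s
    ann = {k: np.full(s, np.nan) for k in ANNOTATION_KEYS}
    if annotations:
        for k, v in annotations.items():
            ann[k] = np.asarray(v, dtype=np.float64)
    if depths is None:
        depths = np.full((s, n), 30, dtype=np.int32)
    else:
        depths = np.asarray(depths, dtype=np.int32)
    if samples is None:
        samples = [f"s{i:03d}" for i in range(n)]
    return VariantTable(
        contigs=[contig],
        contig_lengths={contig: contig_length},
        samples=samples,
        contig_idx=np.zeros(s, dtype=np.int32),
        pos=pos,
        ref=refs,
        alts=list(alts),
        annotations=ann,
        genotypes=genotypes,
        depths=depths,
    )


def two_pop_assignment(samples: list[str], n_obj: int) -> PopulationAssignment:
    labels = {
        s: ("P1" if i < n_obj else "P2") for i, s in enumerate(samples)
    }
    return PopulationAssignment(labels, "P1", "P2")


@pytest.fixture(scope="session")
def small_cohort():
    """One moderately sized simulated cohort shared across read-only tests."""
    from sweepscan.synthetic_data import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_obj=20,
        n_ref=10,
        n_sites=800,
        contig_length=400_000,
        missing_rate=0.02,
        triallelic_fraction=0.02,
        filter_fail_fractions={"QD": 0.05, "FS": 0.05},
        seed=11,
    )
    return simulate_cohort(cfg)
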