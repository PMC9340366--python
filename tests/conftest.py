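"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from chipforge.popfilter import RosterEntry, SampleRoster
from chipforge.variantstore import CallSet, VariantRecord


def make_record(chrom="chr1", pos=100, ref="A", alts=("G",), gts=None,
                info=None, qual=None):
    gts = gts if gts is not None else []
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alts=tuple(alts),
                         genotypes=list(gts), info=dict(info or {}), qual=qual)


def make_callset(rows, samples, roster=None):
    """rows: iterable of (chrom, pos, ref, alts, genotypes[, info])."""
    records = []
    for row in rows:
        chrom, pos, ref, alts, gts = row[:5]
        info = row[5] if len(row) > 5 else {}
        records.append(make_record(chrom, pos, ref, alts, gts, info))
    return CallSet(records=records, samples=list(samples), roster=roster)


def diploid_roster(samples, population="POP"):
    return SampleRoster(entries={
        s: RosterEntry(population=population, role="diploid") for s in samples
    })


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded synthetic cohort shared by read-only tests: reference with
    duplicated segments, haplotypes, DH call set with a replicate."""
    from chipforge import synthdata

    cfg = synthdata.SimulationConfig(
        n_chrom=2, chrom_length_bp=100_000, mutation_density=0.004,
        duplicated_fraction=0.1, psv_het_rate=0.8, effective_size=50,
        genotype_error_rate=0.0, seed=7,
    )
    ref = synthdata.simulate_reference(cfg)
    haps = synthdata.simulate_haplotypes(cfg, ref)
    dh = synthdata.sample_doubled_haploids(
        haps, ref, 12, cfg, replicate_map={"L1_rep": "L1", "L2_rep": "L2"}
    )
    return cfg, ref, haps, dh
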