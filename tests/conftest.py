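"""Shared fixtures: small simulated datasets and hand-written text fixtures.

All data is generated programmatically; session scope keeps the heavier
simulated populations to one build per run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pgsihet.genotype_io import CrossPlan, ParentalGenotypeMatrix
from pgsihet.synthetic import SimulationConfig, simulate_dataset


def make_genotypes(
    rng: np.random.Generator,
    n_sites: int = 50,
    n_samples: int = 6,
    chroms=("A01", "C01"),
    chrom_len: int = 1000,
    inbred: bool = True,
    missing_rate: float = 0.0,
) -> ParentalGenotypeMatrix:
    """Random biallelic genotype matrix for oracle-style tests."""
    per = n_sites // len(chroms)
    chrom_col, pos_col = [], []
    for c in chroms:
        pos = np.sort(rng.choice(chrom_len, size=per, replace=False)) + 1
        chrom_col.extend([c] * per)
        pos_col.extend(pos.tolist())
    n_sites = len(pos_col)
    nt = np.array(["A", "C", "G", "T"], dtype=object)
    ref_idx = rng.integers(0, 4, n_sites)
    alt = nt[(ref_idx + rng.integers(1, 4, n_sites)) % 4]
    if inbred:
        allele = rng.integers(0, 2, size=(n_sites, n_samples)).astype(np.int8)
        calls = np.stack([allele, allele], axis=2)
    else:
        calls = rng.integers(0, 2, size=(n_sites, n_samples, 2)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n_sites, n_samples)) < missing_rate
        calls[mask] = -1
    return ParentalGenotypeMatrix(
        chrom=np.array(chrom_col, dtype=object),
        pos=np.array(pos_col, dtype=np.int64),
        ref=nt[ref_idx],
        alts=[(a,) for a in alt],
        samples=[f"S{i}" for i in range(n_samples)],
        calls=calls,
    )


def make_plan(females, males) -> CrossPlan:
    rows = [(f, m, f"{f}x{m}") for f in females for m in males]
    return CrossPlan(pd.DataFrame(rows, columns=["female_id", "male_id", "hybrid_id"]))


def brute_force_pgsi(parents, plan, windows, literal=False):
    """Independent per-site loop oracle for the windowed similarity index."""
    from pgsihet.windows_pgsi import block_pgsi, site_mark

    resolved = parents.resolve_inbred()
    wf = windows.frame
    values = np.full((len(plan), len(windows)), np.nan)
    n_loci = np.zeros((len(plan), len(windows)), dtype=int)
    for ci, row in enumerate(plan.frame.itertuples(index=False)):
        fi = parents.sample_index(row.female_id)
        mi = parents.sample_index(row.male_id)
        for wi, win in wf.iterrows():
            marks = []
            for s in range(parents.n_sites):
                if parents.chrom[s] != win["chrom"]:
                    continue
                pos0 = parents.pos[s] - 1
                if not (win["start"] <= pos0 < win["end"]):
                    continue
                a, b = resolved[s, fi], resolved[s, mi]
                if a < 0 or b < 0:
                    continue
                alleles = (parents.ref[s],) + tuple(parents.alts[s])
                marks.append(site_mark(alleles[a], alleles[b], parents.ref[s]))
            n_loci[ci, wi] = len(marks)
            if marks:
                values[ci, wi] = block_pgsi(marks, literal=literal)
    return values, n_loci


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 12x4 cross population on a 2 x 1 Mb genome, 2 traits."""
    cfg = SimulationConfig(
        seed=101,
        n_females=12,
        n_males=4,
        chromosomes={"A01": 1_000_000, "C01": 1_000_000},
        n_positive_effect_windows=3,
        n_negative_effect_windows=3,
        traits=("GY", "PH"),
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The study-shaped default population (50 x 8, 4 x 5 Mb genome)."""
    return simulate_dataset(SimulationConfig(seed=7))


TINY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=A01>
##contig=<ID=C01>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\tP3
A01\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t1/1\t0/0
A01\t250\t.\tC\tT\t.\tPASS\t.\tGT\t1/1\t1/1\t./.
A01\t300\t.\tG\tGT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
A01\t400\t.\tT\tA,C\t.\tPASS\t.\tGT\t1/1\t2/2\t0/0
C01\t50\t.\tG\tC\t.\tPASS\t.\tGT\t0/0\t0/0\t1/1
C01\t90\t.\tA\tT\t.\tPASS\t.\tGT\t1/1\t0/0\t0/1
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    """Hand-written VCF: 5 SNPs (one multiallelic), 1 indel, 3 samples."""
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return path
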