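"""Parental genotype I/O, F1 genotype inference and marker coding.

Genotypes live in a :class:`ParentalGenotypeMatrix` — sites x samples allele
pairs, with alleles stored as indices into ``[ref] + alts`` per site and -1
for missing. Parent lines are assumed inbred: a heterozygous parental call
is treated as missing at that site (a strict mode raises instead), because
every downstream quantity (PGSI marks, F1 inference) presumes a single
nucleotide per parent per site.

Additive marker codes follow the minor-allele convention used in genomic
selection: 1 / 0 / -1 for minor-allele homozygote / heterozygote /
major-allele homozygote. Dominance codes are a per-marker mean-centered
heterozygosity indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1


@dataclass(frozen=True)
class VariantSite:
    """A biallelic-or-multiallelic SNP locus on a reference chromosome."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_alleles: tuple[str, ...]

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele,) + self.alt_alleles


@dataclass
class ParentalGenotypeMatrix:
    """SNP calls for a panel of (nominally inbred) lines.

    ``calls`` has shape (n_sites, n_samples, 2); each entry is an allele
    index into ``[ref] + alts`` of the site, or -1 for missing.
    """

    chrom: np.ndarray  # (S,) object
    pos: np.ndarray  # (S,) int64
    ref: np.ndarray  # (S,) object
    alts: list[tuple[str, ...]]  # per site
    samples: list[str]
    calls: np.ndarray  # (S, N, 2) int8
    inbred: bool = True

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (self.n_sites, self.n_samples, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{self.n_sites} sites x {self.n_samples} samples"
            )
        if np.any(self.pos < 1):
            raise ValueError("positions must be 1-based (>= 1)")
        self._check_sorted_unique()

    def _check_sorted_unique(self) -> None:
        # sites must be sorted by (chrom in first-appearance order, pos)
        # with no duplicate (chrom, pos)
        seen: dict[str, int] = {}
        order = np.empty(self.n_sites, dtype=np.int64)
        for i, c in enumerate(self.chrom):
            if c not in seen:
                seen[c] = len(seen)
            order[i] = seen[c]
        if np.any(np.diff(order) < 0):
            raise ValueError("sites are not grouped by chromosome")
        same = np.diff(order) == 0
        dpos = np.diff(self.pos)
        if np.any(same & (dpos <= 0)):
            raise ValueError("sites not strictly sorted by position within chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sites(self) -> Iterator[VariantSite]:
        for i in range(self.n_sites):
            yield VariantSite(
                str(self.chrom[i]), int(self.pos[i]), str(self.ref[i]), tuple(self.alts[i])
            )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in genotype matrix") from None

    def resolve_inbred(self, strict: bool = False) -> np.ndarray:
        """Collapse allele pairs to one allele per parent per site.

        Returns an (n_sites, n_samples) int8 array of allele indices with
        -1 for missing. Heterozygous calls become missing (or raise when
        ``strict``).
        """
        a1 = self.calls[:, :, 0]
        a2 = self.calls[:, :, 1]
        het = (a1 != a2) & (a1 >= 0) & (a2 >= 0)
        n_het = int(het.sum())
        if n_het and strict:
            s, p = np.argwhere(het)[0]
            raise ValueError(
                f"heterozygous call for sample {self.samples[p]!r} at "
                f"{self.chrom[s]}:{self.pos[s]} (strict inbred mode); "
                f"{n_het} heterozygous calls in total"
            )
        if n_het:
            log.info("resolve_inbred: %d heterozygous parental calls set missing", n_het)
        out = np.where((a1 >= 0) & (a2 >= 0) & ~het, a1, MISSING)
        return out.astype(np.int8)

    def select_samples(self, sample_ids: Sequence[str]) -> "ParentalGenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return replace(self, samples=list(sample_ids), calls=self.calls[:, idx, :])


@dataclass
class CodedMarkerMatrix:
    """Individuals x markers numeric marker codes.

    ``coding='additive'``: 1 / 0 / -1 for minor-hom / het / major-hom.
    ``coding='dominance'``: per-marker mean-centered het indicator.
    Missing genotypes remain NaN at this layer (imputation is owned by
    consumers: kinship mean-imputes per marker, PGSI excludes the locus).
    """

    values: np.ndarray  # (N, m) float64, NaN missing
    coding: str
    chrom: np.ndarray  # (m,)
    pos: np.ndarray  # (m,)
    minor_allele: np.ndarray  # (m,) object (nucleotide)
    samples: list[str]
    monomorphic: np.ndarray = field(default=None)  # (m,) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.coding not in ("additive", "dominance"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.monomorphic is None:
            self.monomorphic = np.zeros(self.n_markers, dtype=bool)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def marker_keys(self) -> list[tuple[str, int]]:
        return [(str(c), int(p)) for c, p in zip(self.chrom, self.pos)]


class CrossPlan:
    """Rows of (female_id, male_id, hybrid_id) defining F1 crosses."""

    def __init__(self, frame: pd.DataFrame):
        required = {"female_id", "male_id", "hybrid_id"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"cross plan missing columns: {sorted(missing)}")
        if frame["hybrid_id"].duplicated().any():
            dup = frame.loc[frame["hybrid_id"].duplicated(), "hybrid_id"].iloc[0]
            raise ValueError(f"duplicate hybrid_id in cross plan: {dup!r}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        return self.frame.itertuples(index=False)

    @property
    def hybrid_ids(self) -> list[str]:
        return list(self.frame["hybrid_id"])

    @property
    def parent_ids(self) -> list[str]:
        seen: list[str] = []
        for col in ("female_id", "male_id"):
            for v in self.frame[col]:
                if v not in seen:
                    seen.append(v)
        return seen

    def subset(self, hybrid_ids: Sequence[str]) -> "CrossPlan":
        sel = self.frame[self.frame["hybrid_id"].isin(set(hybrid_ids))]
        return CrossPlan(sel)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def read_cross_plan(path) -> CrossPlan:
    """Read a headered TSV with columns female_id, male_id, hybrid_id."""
    return CrossPlan(pd.read_csv(path, sep="\t", dtype=str))


def read_parent_vcf(path, sample_ids: Sequence[str] | None = None) -> ParentalGenotypeMatrix:
    """Read SNP genotypes from a VCF 4.x file (GT field required).

    Indels and other non-SNP records are skipped (count logged). Sample
    columns are returned in the requested order; a requested sample absent
    from the file is an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    file_samples = list(vcf.samples)
    if sample_ids is None:
        sample_ids = file_samples
        col_idx = np.arange(len(file_samples))
    else:
        missing = [s for s in sample_ids if s not in file_samples]
        if missing:
            raise KeyError(f"samples not present in VCF: {missing}")
        col_idx = np.array([file_samples.index(s) for s in sample_ids])

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    calls: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        alt = tuple(a for a in var.ALT if a not in (".", ""))
        is_snp = len(var.REF) == 1 and len(alt) >= 1 and all(len(a) == 1 for a in alt)
        if not is_snp:
            n_skipped += 1
            continue
        gt = np.array([g[:2] for g in var.genotypes], dtype=np.int8)
        gt = np.where(gt < 0, MISSING, gt)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(alt)
        calls.append(gt[col_idx])
    vcf.close()
    if n_skipped:
        log.info("read_parent_vcf: skipped %d non-SNP records", n_skipped)
    if not poss:
        raise ValueError(f"no SNP records found in {path}")
    call_arr = np.stack(calls, axis=0)
    return ParentalGenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alts=alts,
        samples=list(sample_ids),
        calls=call_arr,
    )


def infer_f1_genotypes(parents: ParentalGenotypeMatrix, plan: CrossPlan) -> ParentalGenotypeMatrix:
    """Derive F1 hybrid genotypes from inbred parents per a cross plan.

    Per site the hybrid receives one allele from each parent; if either
    parent is missing (or heterozygous, resolved per the inbred rule) the
    hybrid call is missing.
    """
    resolved = parents.resolve_inbred()
    fem = [parents.sample_index(r.female_id) for r in plan]
    mal = [parents.sample_index(r.male_id) for r in plan]
    a_f = resolved[:, fem]
    a_m = resolved[:, mal]
    ok = (a_f >= 0) & (a_m >= 0)
    calls = np.full((parents.n_sites, len(plan), 2), MISSING, dtype=np.int8)
    calls[:, :, 0] = np.where(ok, a_f, MISSING)
    calls[:, :, 1] = np.where(ok, a_m, MISSING)
    return ParentalGenotypeMatrix(
        chrom=parents.chrom,
        pos=parents.pos,
        ref=parents.ref,
        alts=parents.alts,
        samples=plan.hybrid_ids,
        calls=calls,
        inbred=False,
    )


def _reduce_biallelic(matrix: ParentalGenotypeMatrix) -> np.ndarray:
    """Collapse calls to {0, 1, -1}: ref, most frequent alt, missing.

    Multiallelic sites keep the reference plus the most frequent alternate
    allele; calls carrying any other alternate become missing.
    """
    calls = matrix.calls.astype(np.int16)
    S = matrix.n_sites
    out = calls.copy()
    multi = np.array([len(a) > 1 for a in matrix.alts])
    for s in np.flatnonzero(multi):
        flat = calls[s].ravel()
        alt_counts = np.bincount(flat[flat >= 1], minlength=len(matrix.alts[s]) + 1)[1:]
        keep = int(np.argmax(alt_counts)) + 1  # ties -> lowest index, deterministic
        row = calls[s]
        row = np.where(row == keep, 1, np.where(row == 0, 0, MISSING))
        out[s] = row
    out = np.where(out > 1, MISSING, out)
    return out.astype(np.int8)


def _major_alt_allele(matrix: ParentalGenotypeMatrix) -> list[str]:
    """Nucleotide of the alt allele retained by the biallelic reduction."""
    out = []
    for s in range(matrix.n_sites):
        alts = matrix.alts[s]
        if len(alts) == 1:
            out.append(alts[0])
        else:
            flat = matrix.calls[s].astype(np.int16).ravel()
            alt_counts = np.bincount(flat[flat >= 1], minlength=len(alts) + 1)[1:]
            out.append(alts[int(np.argmax(alt_counts))])
    return out


def code_additive(genotypes: ParentalGenotypeMatrix) -> CodedMarkerMatrix:
    """Additive codes: 1 / 0 / -1 for minor-hom / het / major-hom.

    The minor allele is the less frequent allele among the coded
    population; a 50/50 tie designates the alternate allele minor.
    Monomorphic markers are coded (all the same value) and flagged.
    """
    reduced = _reduce_biallelic(genotypes)  # (S, N, 2) in {0,1,-1}
    a1 = reduced[:, :, 0].astype(np.float64)
    a2 = reduced[:, :, 1].astype(np.float64)
    ok = (a1 >= 0) & (a2 >= 0)
    dose = np.where(ok, a1 + a2, np.nan)  # alt-allele dosage 0/1/2

    n_alt = np.nansum(dose, axis=1)
    n_called = 2.0 * ok.sum(axis=1)
    n_ref = n_called - n_alt
    minor_is_alt = n_alt <= n_ref  # tie -> alt designated minor
    sign = np.where(minor_is_alt, 1.0, -1.0)
    codes = (dose - 1.0) * sign[:, None]

    mono = (n_alt == 0) | (n_ref == 0)
    alt_nt = _major_alt_allele(genotypes)
    minor_nt = np.array(
        [alt_nt[s] if minor_is_alt[s] else str(genotypes.ref[s]) for s in range(genotypes.n_sites)],
        dtype=object,
    )
    return CodedMarkerMatrix(
        values=codes.T,
        coding="additive",
        chrom=genotypes.chrom.copy(),
        pos=genotypes.pos.copy(),
        minor_allele=minor_nt,
        samples=list(genotypes.samples),
        monomorphic=mono,
    )


def code_dominance(genotypes: ParentalGenotypeMatrix) -> CodedMarkerMatrix:
    """Dominance codes: het -> 1, hom -> 0, then per-marker mean-centering."""
    reduced = _reduce_biallelic(genotypes)
    a1 = reduced[:, :, 0].astype(np.float64)
    a2 = reduced[:, :, 1].astype(np.float64)
    ok = (a1 >= 0) & (a2 >= 0)
    het = np.where(ok, (a1 != a2).astype(np.float64), np.nan)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(het, axis=1, keepdims=True)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    centered = het - mean
    mono = np.nanstd(het, axis=1) == 0
    alt_nt = np.array(_major_alt_allele(genotypes), dtype=object)
    return CodedMarkerMatrix(
        values=centered.T,
        coding="dominance",
        chrom=genotypes.chrom.copy(),
        pos=genotypes.pos.copy(),
        minor_allele=alt_nt,
        samples=list(genotypes.samples),
        monomorphic=mono,
    )


def subsample_markers(matrix: CodedMarkerMatrix, fraction: float, seed: int) -> CodedMarkerMatrix:
    """Uniformly subsample round(fraction * m) markers, preserving order.

    The same seed always yields the same selection.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    m = matrix.n_markers
    n_keep = int(round(fraction * m))
    if n_keep == 0:
        raise ValueError(f"fraction {fraction} of {m} markers selects 0 markers")
    if n_keep == m:
        return matrix
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(m, size=n_keep, replace=False))
    return CodedMarkerMatrix(
        values=matrix.values[:, idx],
        coding=matrix.coding,
        chrom=matrix.chrom[idx],
        pos=matrix.pos[idx],
        minor_allele=matrix.minor_allele[idx],
        samples=list(matrix.samples),
        monomorphic=matrix.monomorphic[idx],
    )
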