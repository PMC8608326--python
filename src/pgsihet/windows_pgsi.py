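"""Genome windows and the parental genetic similarity index (PGSI).

The genome is cut into fixed-width, contiguous, non-overlapping windows
(half-open [start, end), 0-based internally; BED on export). Within a
window, every SNP where both parents of a cross have a resolved call is
marked:

* 2 — the parents carry the same nucleotide,
* 1 — exactly one parent matches the reference, the other differs,
* 0 — the parents differ from the reference and from each other.

The window PGSI is the mark sum divided by twice the number of informative
loci, so identical parents score 1 and maximally divergent parents score
toward 0. A ``literal`` normalization (2 * sum / n) is kept behind a flag
for auditability; it ranges over [0, 4].

Windows with no informative locus for a cross default to PGSI 1.0 (no
observed divergence among the panel's called SNPs) and are flagged; a
``missing`` policy stores NaN instead and leaves imputation to the model
layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from pgsihet.genotype_io import CrossPlan, ParentalGenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class GenomeWindows:
    """Fixed-width genome partition: (chrom, start, end, index_on_chrom)."""

    frame: pd.DataFrame  # columns chrom, start, end, index_on_chrom
    width: int

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "index_on_chrom"}
        if not req <= set(self.frame.columns):
            raise ValueError(f"windows frame must have columns {sorted(req)}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    def keys(self) -> list[str]:
        """Window keys 'chrom:start-end' (0-based half-open, BED-style)."""
        return [
            f"{c}:{s}-{e}"
            for c, s, e in zip(self.frame["chrom"], self.frame["start"], self.frame["end"])
        ]

    def to_bed(self, path) -> None:
        self.frame[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def parse_window_key(key: str) -> tuple[str, int, int]:
    chrom, rest = key.rsplit(":", 1)
    start, end = rest.split("-")
    return chrom, int(start), int(end)


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a chromosome-length table: FAI or two-column (chrom, length) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two tab-separated columns")
    chroms = df.iloc[:, 0].tolist()
    if df.iloc[0, 1].lower() in ("length", "size"):  # tolerate a header row
        df = df.iloc[1:]
        chroms = df.iloc[:, 0].tolist()
    lengths = df.iloc[:, 1].astype(int).tolist()
    if len(set(chroms)) != len(chroms):
        raise ValueError(f"{path}: duplicate chromosome labels")
    return dict(zip(chroms, lengths))


def make_windows(chrom_sizes: dict[str, int], width: int) -> GenomeWindows:
    """Partition each chromosome into ceil(length / width) windows.

    Windows are contiguous half-open [start, end) intervals; the last
    window of a chromosome may be short. ``index_on_chrom`` starts at 1 at
    the chromosome top.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    if len(set(chrom_sizes)) != len(chrom_sizes):
        raise ValueError("duplicate chromosome labels")
    rows = []
    for chrom, length in chrom_sizes.items():
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        starts = np.arange(0, length, width)
        for i, s in enumerate(starts, start=1):
            rows.append((chrom, int(s), int(min(s + width, length)), i))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "index_on_chrom"])
    return GenomeWindows(frame, int(width))


def site_mark(p1_allele: str, p2_allele: str, ref_allele: str) -> int:
    """Mark one SNP site for a parent pair: 2 same, 1 one-matches-ref, 0 neither.

    Identical parental nucleotides score 2 regardless of the reference
    (the identity rule takes precedence).
    """
    if p1_allele == p2_allele:
        return 2
    if p1_allele == ref_allele or p2_allele == ref_allele:
        return 1
    return 0


def block_pgsi(marks: Sequence[int], literal: bool = False) -> float:
    """Aggregate per-site marks into a window PGSI.

    Default: sum(marks) / (2 n) in [0, 1]. ``literal=True`` computes
    2 * sum(marks) / n in [0, 4]. An empty mark list returns NaN; window
    level empty-cell policy is applied by :func:`compute_pgsi_matrix`.
    """
    marks = np.asarray(list(marks), dtype=np.float64)
    if marks.size == 0:
        return float("nan")
    if np.any((marks < 0) | (marks > 2)):
        raise ValueError("marks must be in {0, 1, 2}")
    if literal:
        return float(2.0 * marks.sum() / marks.size)
    return float(marks.sum() / (2.0 * marks.size))


@dataclass
class PGSIMatrix:
    """Crosses x windows PGSI values with informative-locus counts."""

    values: np.ndarray  # (n_crosses, n_windows) float64
    n_loci: np.ndarray  # (n_crosses, n_windows) int64
    windows: GenomeWindows
    cross_ids: list[str]
    empty_policy: str = "identity"
    literal: bool = False

    def __post_init__(self) -> None:
        if self.values.shape != self.n_loci.shape:
            raise ValueError("values / n_loci shape mismatch")
        if self.values.shape != (len(self.cross_ids), len(self.windows)):
            raise ValueError("PGSI matrix shape inconsistent with crosses x windows")

    @property
    def empty_cells(self) -> np.ndarray:
        return self.n_loci == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cross_ids, columns=self.windows.keys())

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "cross_id"
        df.to_csv(path, sep="\t")


def _window_index_per_site(
    genotypes: ParentalGenotypeMatrix, windows: GenomeWindows
) -> np.ndarray:
    """Map each site to a global window index (-1 when no window covers it)."""
    wf = windows.frame
    out = np.full(genotypes.n_sites, -1, dtype=np.int64)
    for chrom in windows.chroms:
        wsel = wf.index[wf["chrom"] == chrom].to_numpy()
        starts = wf.loc[wsel, "start"].to_numpy()
        ends = wf.loc[wsel, "end"].to_numpy()
        ssel = np.flatnonzero(genotypes.chrom == chrom)
        if ssel.size == 0:
            continue
        pos0 = genotypes.pos[ssel] - 1  # 1-based VCF -> 0-based interval
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        out[ssel[ok]] = wsel[j[ok]]
    return out


def compute_pgsi_matrix(
    parents: ParentalGenotypeMatrix,
    plan: CrossPlan,
    windows: GenomeWindows,
    empty_policy: str = "identity",
    literal: bool = False,
) -> PGSIMatrix:
    """Compute the PGSI for every cross and every window.

    Sites where either parent is missing (after inbred resolution) are
    excluded from both the mark sum and the locus count. PGSI is symmetric
    in the two parents.
    """
    if empty_policy not in ("identity", "missing"):
        raise ValueError(f"unknown empty_policy {empty_policy!r}")
    if not set(windows.chroms) & set(np.unique(parents.chrom)):
        raise ValueError("window chromosomes and genotype chromosomes are disjoint")
    resolved = parents.resolve_inbred()
    win_of = _window_index_per_site(parents, windows)
    in_win = win_of >= 0
    n_w = len(windows)
    n_c = len(plan)
    values = np.empty((n_c, n_w), dtype=np.float64)
    n_loci = np.zeros((n_c, n_w), dtype=np.int64)
    fem = [parents.sample_index(r.female_id) for r in plan]
    mal = [parents.sample_index(r.male_id) for r in plan]
    for ci in range(n_c):
        a = resolved[:, fem[ci]]
        b = resolved[:, mal[ci]]
        valid = (a >= 0) & (b >= 0) & in_win
        eq = a == b
        has_ref = (a == 0) | (b == 0)
        marks = np.where(eq, 2.0, np.where(has_ref, 1.0, 0.0))
        w = win_of[valid]
        sums = np.bincount(w, weights=marks[valid], minlength=n_w)
        counts = np.bincount(w, minlength=n_w)
        n_loci[ci] = counts
        with np.errstate(invalid="ignore", divide="ignore"):
            if literal:
                values[ci] = 2.0 * sums / counts
            else:
                values[ci] = sums / (2.0 * counts)
    empty = n_loci == 0
    if empty.any():
        log.info("compute_pgsi_matrix: %d empty cross x window cells", int(empty.sum()))
    if empty_policy == "identity":
        fill = 2.0 * 2.0 if literal else 1.0  # identical parents under each scale
        values[empty] = fill
    else:
        values[empty] = np.nan
    return PGSIMatrix(
        values=values,
        n_loci=n_loci,
        windows=windows,
        cross_ids=plan.hybrid_ids,
        empty_policy=empty_policy,
        literal=literal,
    )


def read_pgsi_tsv(path) -> pd.DataFrame:
    """Read a PGSI TSV written by :meth:`PGSIMatrix.to_tsv`."""
    return pd.read_csv(path, sep="\t", index_col="cross_id")
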