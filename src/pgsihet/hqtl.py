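"""h-QTL extraction, naming and mapping from window-level LASSO fits.

Every window retained by the LASSO heterosis model is an h-QTL; the
top 10% and bottom 10% of the re-estimated regression coefficients are
high-impact h-QTLs. Because the features are PGSI (similarity) values,
the effect-sign convention is inverted relative to the coefficient: a
*positive* effect (more parental divergence, more heterosis) corresponds
to a negative PGSI coefficient, and vice versa. Both the raw coefficient
and the label are always exported.

Names follow the Chr.<chrom>-<NN> convention: h-QTLs are numbered from
the top of each chromosome, zero-padded to at least two digits.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from pgsihet.gs_models import LassoFit
from pgsihet.windows_pgsi import GenomeWindows, PGSIMatrix, parse_window_key

log = logging.getLogger(__name__)

_PLACED_RE = re.compile(r"^(chr\.?)?[A-Za-z]{0,3}\d+$", re.IGNORECASE)


@dataclass
class WindowCorrelation:
    """Pearson correlation of one window's PGSI with heterosis across crosses."""

    window_key: str
    chrom: str
    trait: str
    heterosis_type: str
    r: float
    n: int


def window_heterosis_correlations(
    pgsi: PGSIMatrix | pd.DataFrame,
    heterosis: pd.DataFrame,
    trait: str,
    which: str = "HPH",
) -> pd.DataFrame:
    """Per-window Pearson r between PGSI and heterosis across crosses.

    Returns a frame (window_key, chrom, start, end, r, n). Constant
    columns give NaN r.
    """
    feats = pgsi.to_frame() if isinstance(pgsi, PGSIMatrix) else pgsi
    col = f"{trait}_{which}"
    if col not in heterosis.columns:
        raise KeyError(f"no column {col!r} in heterosis table")
    h = heterosis[col].dropna()
    shared = [i for i in feats.index if i in set(h.index)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} crosses shared between PGSI and heterosis")
    F = feats.loc[shared]
    hv = h.loc[shared]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = F.corrwith(hv, method="pearson")
    n = F.notna().sum(axis=0)
    rows = []
    for key in feats.columns:
        chrom, start, end = parse_window_key(key)
        rows.append((key, chrom, start, end, float(r[key]), int(n[key])))
    return pd.DataFrame(rows, columns=["window_key", "chrom", "start", "end", "r", "n"])


def chromosome_influence(correlations: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-chromosome influence: the stacked absolute correlation coefficients.

    Missing r contributes 0. Also returns subgenome aggregates keyed by the
    leading letter of the chromosome name (A vs C in *B. napus*).
    """
    df = correlations.copy()
    df["abs_r"] = df["r"].abs().fillna(0.0)
    per_chrom = df.groupby("chrom", sort=False)["abs_r"].sum()
    per_chrom.name = "influence"
    sub = per_chrom.groupby(lambda c: str(c)[0].upper()).sum()
    sub.name = "influence"
    return per_chrom, sub


@dataclass
class HqtlRecord:
    """One named genomic window with its heterosis coefficient."""

    name: str  # assigned by name_hqtls; '' until then
    chrom: str
    start: int
    end: int
    coefficient: float  # re-estimated coefficient per unit raw PGSI
    effect: str  # 'positive' (coef < 0) | 'negative' (coef > 0)
    impact: str  # 'high' | 'regular'
    trait: str
    heterosis_type: str
    mappable: bool = True

    @property
    def window_key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def extract_hqtls(
    fit: LassoFit,
    windows: GenomeWindows,
    trait: str,
    which: str = "HPH",
    high_impact_fraction: float = 0.1,
) -> list[HqtlRecord]:
    """Turn every selected window of a LASSO fit into an h-QTL record.

    High-impact h-QTLs are the top ceil(f*k) and bottom ceil(f*k) of the
    re-estimated coefficients (ranked by value); boundary ties are broken
    by |coefficient| then genomic order. Windows on chromosomes that do
    not look like placed chromosomes are retained but flagged unmappable.
    """
    if fit.intercept_only or fit.selected.size == 0:
        log.warning("extract_hqtls: intercept-only fit, no h-QTLs")
        return []
    coefs = fit.coefficients_original_scale()
    keys = list(coefs.index)
    k = len(keys)
    n_hi = math.ceil(high_impact_fraction * k)
    # rank by coefficient value; ties by |coefficient| (larger wins) then
    # genomic order (earlier wins)
    parsed = [parse_window_key(kk) for kk in keys]
    top_order = sorted(
        range(k),
        key=lambda i: (-coefs.iloc[i], -abs(coefs.iloc[i]), parsed[i][0], parsed[i][1]),
    )
    bottom_order = sorted(
        range(k),
        key=lambda i: (coefs.iloc[i], -abs(coefs.iloc[i]), parsed[i][0], parsed[i][1]),
    )
    top = set(top_order[:n_hi])
    bottom = set(bottom_order[:n_hi])
    records = []
    for i, key in enumerate(keys):
        chrom, start, end = parsed[i]
        c = float(coefs.iloc[i])
        records.append(
            HqtlRecord(
                name="",
                chrom=chrom,
                start=start,
                end=end,
                coefficient=c,
                effect="positive" if c < 0 else "negative",
                impact="high" if (i in top or i in bottom) else "regular",
                trait=trait,
                heterosis_type=which,
                mappable=bool(_PLACED_RE.match(chrom)),
            )
        )
    return records


def name_hqtls(records: list[HqtlRecord]) -> list[HqtlRecord]:
    """Assign Chr.<chrom>-<NN> names, numbering top-to-bottom per chromosome."""
    by_chrom: dict[str, list[HqtlRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    named = []
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda r: r.start)
        pad = max(2, len(str(len(recs))))
        for i, rec in enumerate(recs, start=1):
            named.append(replace(rec, name=f"Chr.{chrom}-{i:0{pad}d}"))
    named.sort(key=lambda r: (r.chrom, r.start))
    return named


def hqtls_to_frame(records: list[HqtlRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "coefficient": r.coefficient,
                "effect": r.effect,
                "impact": r.impact,
                "trait": r.trait,
                "heterosis_type": r.heterosis_type,
                "mappable": r.mappable,
            }
            for r in records
        ]
    )


def hqtls_to_bed(records: list[HqtlRecord], path) -> None:
    frame = hqtls_to_frame(records)
    frame = frame[frame["mappable"]]
    frame[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", header=False, index=False)


def genes_in_windows(records: list[HqtlRecord], annotation_path) -> dict[str, list[str]]:
    """Genes whose span intersects each h-QTL window (half-open intervals).

    ``annotation_path`` is a GFF3 with ``gene`` features. Returns a map of
    h-QTL name (or window key when unnamed) to gene ID list. Chromosome
    name mismatches are reported with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(annotation_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("ID", [g.id])[0]
        genes.append((g.seqid, g.start - 1, g.end, gid))  # GFF3 1-based closed -> 0-based half-open
    gene_chroms = {g[0] for g in genes}
    rec_chroms = {r.chrom for r in records}
    unmatched = rec_chroms - gene_chroms
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} h-QTL chromosome(s) absent from annotation: "
            f"{sorted(unmatched)[:5]}"
        )
    out: dict[str, list[str]] = {}
    for rec in records:
        hits = [
            gid
            for chrom, gs, ge, gid in genes
            if chrom == rec.chrom and gs < rec.end and ge > rec.start
        ]
        out[rec.name or rec.window_key] = hits
    return out
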