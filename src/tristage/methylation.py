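"""Promoter methylation scoring from immunoprecipitation read intervals.

The methylation level of a genomic region is quantified as extended reads
per kilobase: each sequenced fragment is extended to a fixed length from
its 5' end and counted against a region when it overlaps by at least one
base.  Differentially methylated regions (DMRs) are called per pairwise
group contrast at a linear fold change >= 1.5 and t-test p <= 0.05.
Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: pseudocount in read units added to each replicate count before per-kb
#: scaling, stabilizing fold changes at low coverage
PSEUDOCOUNT_READS = 0.5


@dataclass(frozen=True)
class GenomicRegion:
    chrom: str
    start: int
    end: int
    name: str | None = None  # gene symbol for promoter regions

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    @property
    def length_kb(self) -> float:
        return (self.end - self.start) / 1000.0


@dataclass(frozen=True)
class MethylRegion:
    """A region with per-group scores and its differential-methylation call."""

    region: GenomicRegion
    scores_a: tuple[float, ...]
    scores_b: tuple[float, ...]
    fold_change: float  # linear, >= 1
    p_value: float
    differential: bool
    direction: str  # "up" if group b more methylated, else "down"


# ---- BED I/O ----------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED file into columns chrom/start/end[/name[/score[/strand]]]."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    frame.columns = names[: frame.shape[1]]
    frame["start"] = frame["start"].astype(int)
    frame["end"] = frame["end"].astype(int)
    return frame


def write_bed(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", header=False, index=False)


def regions_from_bed(path) -> list[GenomicRegion]:
    frame = read_bed(path)
    name = frame["name"] if "name" in frame.columns else [None] * len(frame)
    return [
        GenomicRegion(c, s, e, n)
        for c, s, e, n in zip(frame["chrom"], frame["start"], frame["end"], name)
    ]


# ---- scoring ----------------------------------------------------------------

def extend_reads(reads: pd.DataFrame, extension_length: int = 300) -> pd.DataFrame:
    """Extend each read to ``extension_length`` bases from its 5' end.

    Plus-strand (or unstranded) reads extend rightward from ``start``;
    minus-strand reads extend leftward from ``end``, clipped at 0.
    """
    if extension_length < 0:
        raise ValueError("extension length must be non-negative")
    out = reads.copy()
    if "strand" in out.columns:
        minus = out["strand"] == "-"
    else:
        minus = pd.Series(False, index=out.index)
    out.loc[~minus, "end"] = out.loc[~minus, "start"] + extension_length
    out.loc[minus, "start"] = (out.loc[minus, "end"] - extension_length).clip(lower=0)
    return out


def methylation_score(extended: pd.DataFrame, region: GenomicRegion) -> float:
    """Extended reads per kb: overlap count (>= 1 bp) over region length."""
    if region.end <= region.start:
        raise ValueError("zero-length region")
    on_chrom = extended[extended["chrom"] == region.chrom]
    overlaps = (on_chrom["start"] < region.end) & (on_chrom["end"] > region.start)
    return float(overlaps.sum()) / region.length_kb


def score_regions(
    read_sets: list[pd.DataFrame],
    regions: list[GenomicRegion],
    extension_length: int = 300,
) -> np.ndarray:
    """Score every region against every replicate read set (regions × reps)."""
    extended = [extend_reads(r, extension_length) for r in read_sets]
    return np.array(
        [[methylation_score(e, region) for e in extended] for region in regions]
    )


def screen_dmrs(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    regions: list[GenomicRegion],
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    pseudocount: float = PSEUDOCOUNT_READS,
) -> list[MethylRegion]:
    """Call DMRs between two groups of replicate score vectors.

    Fold change is max(mean_a, mean_b)/min(mean_a, mean_b) on pseudocounted
    scores (so it is always >= 1 and direction-free); the flag requires
    FC >= ``fc_threshold`` (inclusive) and t-test p <= ``p_threshold``.
    Regions with zero reads in every replicate of both groups are skipped:
    their fold change is undefined.
    """
    scores_a = np.atleast_2d(np.asarray(scores_a, dtype=float))
    scores_b = np.atleast_2d(np.asarray(scores_b, dtype=float))
    if scores_a.shape[1] < 2 or scores_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    results: list[MethylRegion] = []
    for i, region in enumerate(regions):
        a, b = scores_a[i], scores_b[i]
        if not a.any() and not b.any():
            continue  # FC undefined with no signal anywhere
        pseudo = pseudocount / region.length_kb
        mean_a, mean_b = a.mean() + pseudo, b.mean() + pseudo
        fc = max(mean_a, mean_b) / min(mean_a, mean_b)
        if a.var() == 0 and b.var() == 0:
            p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
        results.append(
            MethylRegion(
                region,
                tuple(a),
                tuple(b),
                float(fc),
                p,
                fc >= fc_threshold and p <= p_threshold,
                "up" if mean_b > mean_a else "down",
            )
        )
    return results


def dmrs_to_frame(dmrs: list[MethylRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                d.region.chrom,
                d.region.start,
                d.region.end,
                d.region.name,
                ",".join(f"{s:g}" for s in d.scores_a),
                ",".join(f"{s:g}" for s in d.scores_b),
                d.fold_change,
                d.p_value,
                d.differential,
                d.direction,
            )
            for d in dmrs
        ],
        columns=[
            "chrom", "start", "end", "gene",
            "scores_a", "scores_b", "fold_change", "p_value",
            "differential", "direction",
        ],
    )


def annotate_promoter_methylation(candidates, dmr_tests: list[MethylRegion]):
    """Attach the minimum promoter-test p-value to each candidate gene.

    ``dmr_tests`` are per-promoter test results whose region names are gene
    symbols.  A candidate whose promoters were tested gets the minimum
    p-value over them; candidates with no tested promoter are marked
    untested (never significant).  Returns the same candidate objects,
    mutated in place, for convenience.
    """
    by_gene: dict[str, float] = {}
    for d in dmr_tests:
        if d.region.name is None:
            continue
        prev = by_gene.get(d.region.name)
        if prev is None or d.p_value < prev:
            by_gene[d.region.name] = d.p_value
    for c in candidates:
        if c.gene in by_gene:
            c.drmp_p = by_gene[c.gene]
            c.drmp_tested = True
        else:
            c.drmp_p = None
            c.drmp_tested = False
    return candidates


def promoters_from_genes(
    genes: pd.DataFrame, upstream: int = 2000, downstream: int = 500
) -> list[GenomicRegion]:
    """Derive promoter windows (TSS -upstream/+downstream) from a gene BED.

    Strand-aware: the TSS is ``start`` on the plus strand and ``end`` on the
    minus strand.  Windows are clipped at coordinate 0.
    """
    promoters = []
    for row in genes.itertuples(index=False):
        strand = getattr(row, "strand", "+")
        if strand == "-":
            start, end = row.end - downstream, row.end + upstream
        else:
            start, end = row.start - upstream, row.start + downstream
        promoters.append(
            GenomicRegion(row.chrom, max(start, 0), end, getattr(row, "name", None))
        )
    return promoters
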