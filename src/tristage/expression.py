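"""Expression-matrix handling and differential-expression screening.

The experimental design is a three-group time course — baseline (C, week 0),
early (M, week 12) and advanced (E, week 28) — with replicate log2-scale
intensity profiles per group.  Genes are screened per pairwise comparison
(M vs C, E vs C, E vs M) with a fold-change-plus-t-test rule and partitioned
into six directional subsets (MvCup, MvCdown, EvCup, EvCdown, EvMup, EvMdown).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("C", "M", "E")

#: the three pairwise comparisons, oriented second-named-minus-first:
#: "MvC" means mean(M) - mean(C) on the log2 scale.
COMPARISONS = ("MvC", "EvC", "EvM")

#: directional subset labels matching the candidate-table vocabulary.
SUBSET_LABELS = ("MvCup", "MvCdown", "EvCup", "EvCdown", "EvMup", "EvMdown")

_COMPARISON_GROUPS = {"MvC": ("C", "M"), "EvC": ("C", "E"), "EvM": ("M", "E")}


def comparison_groups(comparison: str) -> tuple[str, str]:
    """Return (reference group, test group) for a comparison label."""
    try:
        return _COMPARISON_GROUPS[comparison]
    except KeyError:
        raise ValueError(f"unknown comparison {comparison!r}") from None


@dataclass
class ExpressionMatrix:
    """Genes × samples intensity matrix with group labels and detection flags.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, index = gene IDs, columns = sample IDs.
    groups
        Series mapping each sample ID to its group label (C, M or E).
    detected
        Optional boolean DataFrame of the same shape as ``values``; missing
        means every value is considered detected.
    """

    values: pd.DataFrame
    groups: pd.Series
    detected: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene IDs")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        self.groups = self.groups.loc[self.values.columns]
        if self.detected is not None:
            if self.detected.shape != self.values.shape:
                raise ValueError("detection flags shape mismatch")
            self.detected = self.detected.loc[self.values.index, self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_means(self, order: tuple[str, ...] = GROUPS) -> pd.DataFrame:
        """Per-gene mean log2 intensity per group, columns ordered like `order`."""
        cols = {g: self.values[self.group_samples(g)].mean(axis=1) for g in order}
        return pd.DataFrame(cols)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        det = None if self.detected is None else self.detected.loc[genes]
        return ExpressionMatrix(self.values.loc[genes], self.groups, det)

    # ---- TSV round trip (matrix: first column gene ID; sheet: sample, group)

    def to_tsv(self, matrix_path, samples_path, detection_path=None) -> None:
        self.values.rename_axis("gene").to_csv(matrix_path, sep="\t")
        self.groups.rename("group").rename_axis("sample").to_csv(samples_path, sep="\t")
        if detection_path is not None and self.detected is not None:
            self.detected.astype(int).rename_axis("gene").to_csv(detection_path, sep="\t")

    @classmethod
    def from_tsv(cls, matrix_path, samples_path, detection_path=None) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t", index_col=0)
        groups = sheet["group"].astype(str)
        detected = None
        if detection_path is not None:
            detected = pd.read_csv(detection_path, sep="\t", index_col=0).astype(bool)
        return cls(values, groups, detected)


@dataclass(frozen=True)
class DEGRecord:
    """One differentially-expressed-gene call for one pairwise comparison."""

    gene: str
    comparison: str
    log2_fc: float
    p_value: float

    @property
    def direction(self) -> str:
        return "up" if self.log2_fc > 0 else "down"

    @property
    def subset(self) -> str:
        return f"{self.comparison}{self.direction}"


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples to a common reference distribution.

    Each sample's sorted values are replaced by the across-sample mean of
    sorted values; within-sample ranks are preserved.  Ties within a sample
    receive the mean of the reference values at their (average) rank
    positions, so the transform is deterministic and idempotent.
    """
    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values are not supported")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")  # 1-based, ties averaged
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    values = pd.DataFrame(out, index=matrix.genes, columns=matrix.samples)
    return replace(matrix, values=values)


def detection_filter(matrix: ExpressionMatrix, min_detected: int = 6) -> ExpressionMatrix:
    """Retain genes detected in at least ``min_detected`` samples (default 6 of 9)."""
    if min_detected > len(matrix.samples):
        raise ValueError("min_detected exceeds the number of samples")
    if matrix.detected is None:
        return matrix
    keep = matrix.detected.sum(axis=1) >= min_detected
    return matrix.subset_genes(matrix.genes[keep])


def _ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise two-sample t-test p-values with degenerate-variance handling.

    Zero within-group variance in both groups: p = 1 when the means are
    equal (no call possible) and p = 0 when they differ (infinitely strong
    evidence in the zero-noise limit).
    """
    with warnings.catch_warnings():
        # zero-variance rows trigger precision warnings; they are overridden below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return p


def screen_degs(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    equal_var: bool = False,
) -> list[DEGRecord]:
    """Screen DEGs for one pairwise comparison (``group_b`` minus ``group_a``).

    A gene is called iff |log2 FC| >= ``fc_threshold`` (inclusive) and the
    two-sample t-test p-value <= ``p_threshold``.  Welch's t-test by default
    (``equal_var=False``); raw p-values, no multiple-testing correction.
    """
    a = matrix.values[matrix.group_samples(group_a)].to_numpy(dtype=float)
    b = matrix.values[matrix.group_samples(group_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    fc = b.mean(axis=1) - a.mean(axis=1)
    p = _ttest(a, b, equal_var=equal_var)
    comparison = next(
        (c for c, gs in _COMPARISON_GROUPS.items() if gs == (group_a, group_b)),
        f"{group_b}v{group_a}",
    )
    called = (np.abs(fc) >= fc_threshold) & (p <= p_threshold)
    return [
        DEGRecord(gene, comparison, float(fc[i]), float(p[i]))
        for i, gene in enumerate(matrix.genes)
        if called[i]
    ]


def screen_all_comparisons(matrix: ExpressionMatrix, **kwargs) -> list[DEGRecord]:
    """Screen the three canonical comparisons MvC, EvC, EvM."""
    records: list[DEGRecord] = []
    for comparison in COMPARISONS:
        ref, test = comparison_groups(comparison)
        records.extend(screen_degs(matrix, ref, test, **kwargs))
    return records


def deg_subsets(records: list[DEGRecord]) -> dict[str, set[str]]:
    """Partition DEG records into the six directional subsets.

    A gene may appear in several comparisons but in at most one direction
    per comparison; conflicting duplicates raise.
    """
    seen: dict[tuple[str, str], str] = {}
    subsets: dict[str, set[str]] = {label: set() for label in SUBSET_LABELS}
    for rec in records:
        key = (rec.gene, rec.comparison)
        if key in seen and seen[key] != rec.direction:
            raise ValueError(f"conflicting directions for {rec.gene} in {rec.comparison}")
        seen[key] = rec.direction
        subsets.setdefault(rec.subset, set()).add(rec.gene)
    return subsets


def records_to_frame(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene, r.comparison, r.log2_fc, r.p_value, r.direction) for r in records],
        columns=["gene", "comparison", "log2_fc", "p_value", "direction"],
    )
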