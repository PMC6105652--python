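"""Wet-lab validation statistics: qPCR, capillary western, immunostaining.

Relative transcript abundance from qRT-PCR uses the 2^-ddCt method (target
Ct normalized to a reference gene, then to a calibrator group).  Capillary
western quantifications are compared by one-way ANOVA.  Immunostaining is
summarized by the red-intensity index Ri (integrated red-channel pixel
counts over a high-intensity window) and called positive against the mean
Ri of negative-control fields.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def ddct_quantify(table: pd.DataFrame, calibrator_group: str) -> pd.Series:
    """Per-group relative expression by the 2^-ddCt method.

    ``table`` needs columns sample, group, ct_target, ct_reference.
    dCt = Ct_target - Ct_reference per sample; ddCt = group mean dCt minus
    calibrator mean dCt; relative expression = 2^-ddCt (calibrator = 1.0).
    """
    required = {"group", "ct_target", "ct_reference"}
    if not required <= set(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if table[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct values")
    if calibrator_group not in set(table["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent")
    dct = table["ct_target"] - table["ct_reference"]
    group_dct = dct.groupby(table["group"]).mean()
    ddct = group_dct - group_dct[calibrator_group]
    return (2.0 ** -ddct).rename("relative_expression")


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MS_between / MS_within.

    Degenerate inputs: with zero within-group variance and equal means the
    data carry no contrast, so F = 0 and p = 1; with zero within-group
    variance and unequal means separation is perfect, so F = inf and p = 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    means = [a.mean() for a in arrays]
    if within == 0:
        if np.allclose(means, means[0]):
            return 0.0, 1.0
        return float("inf"), 0.0
    grand = np.concatenate(arrays).mean()
    between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    df_between = len(arrays) - 1
    df_within = sum(len(a) for a in arrays) - len(arrays)
    f = (between / df_between) / (within / df_within)
    return float(f), float(stats.f.sf(f, df_between, df_within))


def ri_index(histogram: np.ndarray, low: int = 200, high: int = 255) -> int:
    """Red-intensity index: total pixel count in bins [low, high] inclusive."""
    histogram = np.asarray(histogram)
    if histogram.shape != (256,) or (histogram < 0).any():
        raise ValueError("histogram must be 256 non-negative counts")
    if not (0 <= low <= high <= 255):
        raise ValueError("invalid integration interval")
    return int(histogram[low : high + 1].sum())


def read_histogram(path) -> np.ndarray:
    """Load a plain 256-line pixel-count file (one bin count per line)."""
    counts = np.loadtxt(path, dtype=int)
    if counts.shape != (256,):
        raise ValueError("expected exactly 256 bin counts")
    return counts


def positivity_call(
    sample_ris: np.ndarray, control_ris: np.ndarray, alpha: float = 0.05
) -> bool:
    """Positive iff sample fields stain higher than the negative-control MRV.

    Field-level Ri values are compared by a one-sided Welch t-test; positive
    requires mean(sample) > mean(control) and p <= alpha.
    """
    sample = np.asarray(sample_ris, dtype=float)
    control = np.asarray(control_ris, dtype=float)
    if len(sample) < 2 or len(control) < 2:
        raise ValueError("need >= 2 visual fields per side")
    if sample.mean() <= control.mean():
        return False
    if sample.var() == 0 and control.var() == 0:
        return True  # perfectly separated, no sampling noise
    p = stats.ttest_ind(sample, control, equal_var=False, alternative="greater").pvalue
    return bool(p <= alpha)
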