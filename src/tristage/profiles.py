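"""Short time-series model-profile clustering with permutation significance.

Re-implements the short-time-series expression mining approach: candidate
model profiles are integer level templates starting at 0 with bounded unit
change per step; a distinct subset is selected greedily; genes are assigned
to their nearest profile under correlation distance; and profile
significance is assessed against a null built from all T! permutations of
time-point order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
import pandas as pd
from scipy import stats

from .expression import GROUPS, ExpressionMatrix


@dataclass(frozen=True)
class ModelProfile:
    """Integer-level temporal template; ``levels[0]`` is always 0."""

    id: int
    levels: tuple[int, ...]

    @property
    def is_flat(self) -> bool:
        return len(set(self.levels)) == 1


@dataclass(frozen=True)
class ProfileAssignment:
    gene: str
    profile_id: int
    distance: float  # 1 - Pearson correlation, in [0, 2]


@dataclass(frozen=True)
class ProfileSignificance:
    profile_id: int
    n_assigned: int
    n_expected: float
    p_raw: float
    p_adjusted: float
    significant: bool


def gene_temporal_vector(matrix: ExpressionMatrix, order: tuple[str, ...] = GROUPS) -> pd.DataFrame:
    """Per-gene group-mean vector re-zeroed at the first time point."""
    means = matrix.group_means(order)
    return means.sub(means.iloc[:, 0], axis=0)


def enumerate_profiles(T: int, c: int = 2) -> list[ModelProfile]:
    """All level sequences of length T starting at 0 with |step| <= c.

    Count is (2c+1)^(T-1).  IDs follow lexicographic order of the level
    tuples, which is stable across runs and documented as the enumeration
    convention.
    """
    if T < 1 or c < 1:
        raise ValueError("need T >= 1 and c >= 1")
    level_tuples = []
    for steps in product(range(-c, c + 1), repeat=T - 1):
        levels = [0]
        for s in steps:
            levels.append(levels[-1] + s)
        level_tuples.append(tuple(levels))
    level_tuples.sort()
    return [ModelProfile(i, levels) for i, levels in enumerate(level_tuples)]


def _profile_distance(p: ModelProfile, q: ModelProfile) -> float:
    """1 - Pearson between level vectors; Euclidean fallback when either is flat."""
    if p.is_flat or q.is_flat:
        return float(np.linalg.norm(np.subtract(p.levels, q.levels)))
    r = np.corrcoef(p.levels, q.levels)[0, 1]
    return float(1.0 - r)


def select_distinct_profiles(candidates: list[ModelProfile], m: int) -> list[ModelProfile]:
    """Greedy max-min selection of m mutually distinct profiles.

    Starts from the flat profile; each round adds the candidate with the
    largest minimum distance to the chosen set, tie-broken by lowest id.
    Returns all candidates when m >= |candidates|.
    """
    if m < 2:
        raise ValueError("need m >= 2")
    if m >= len(candidates):
        return sorted(candidates, key=lambda p: p.id)
    pool = sorted(candidates, key=lambda p: p.id)
    flat = next((p for p in pool if p.is_flat), pool[0])
    chosen = [flat]
    remaining = [p for p in pool if p is not flat]
    while len(chosen) < m:
        best = max(
            remaining,
            key=lambda p: (min(_profile_distance(p, q) for q in chosen), -p.id),
        )
        chosen.append(best)
        remaining.remove(best)
    return sorted(chosen, key=lambda p: p.id)


def _assign_matrix(vectors: np.ndarray, profiles: list[ModelProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized nearest-profile assignment under 1 - Pearson distance.

    Returns (profile index per gene, distance per gene).  Zero-variance gene
    vectors go to the flat profile (distance 0 by convention); profiles with
    zero variance are unreachable for non-flat genes (correlation undefined).
    Ties break toward the lowest profile id.
    """
    n, T = vectors.shape
    P = np.array([p.levels for p in profiles], dtype=float)
    flat_idx = next((i for i, p in enumerate(profiles) if p.is_flat), None)

    vc = vectors - vectors.mean(axis=1, keepdims=True)
    vnorm = np.linalg.norm(vc, axis=1)
    pc = P - P.mean(axis=1, keepdims=True)
    pnorm = np.linalg.norm(pc, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (vc @ pc.T) / np.outer(vnorm, pnorm)
    dist = 1.0 - corr
    dist[:, pnorm == 0] = np.inf  # flat profiles unreachable via correlation

    # profiles are in ascending-id order, so argmin's first-hit rule is the
    # lowest-id tie-break
    idx = np.argmin(np.round(dist, 12), axis=1)
    best = dist[np.arange(n), idx]

    flat_gene = vnorm == 0
    if flat_gene.any():
        if flat_idx is None:
            raise ValueError("zero-variance gene vectors need a flat profile")
        idx[flat_gene] = flat_idx
        best[flat_gene] = 0.0
    return idx, best


def assign_genes(vectors: pd.DataFrame, profiles: list[ModelProfile]) -> list[ProfileAssignment]:
    """Assign every gene to its single nearest selected profile."""
    if not profiles:
        raise ValueError("no profiles to assign to")
    profiles = sorted(profiles, key=lambda p: p.id)
    idx, dist = _assign_matrix(vectors.to_numpy(dtype=float), profiles)
    return [
        ProfileAssignment(gene, profiles[idx[i]].id, float(dist[i]))
        for i, gene in enumerate(vectors.index)
    ]


def permutation_significance(
    vectors: pd.DataFrame,
    profiles: list[ModelProfile],
    alpha: float = 0.05,
    perms: list[tuple[int, ...]] | None = None,
) -> list[ProfileSignificance]:
    """Profile-level significance against the time-permutation null.

    For every permutation of time-point order the gene vectors are re-zeroed
    at their new first point and re-assigned; the expected count per profile
    is the mean over permutations.  p_raw is the upper-tail binomial
    probability of observing >= n_assigned assignments out of n_genes at
    success rate n_expected/n_genes, Bonferroni-adjusted over the selected
    profiles.
    """
    profiles = sorted(profiles, key=lambda p: p.id)
    V = vectors.to_numpy(dtype=float)
    n_genes, T = V.shape
    if perms is None:
        perms = list(permutations(range(T)))

    observed_idx, _ = _assign_matrix(V, profiles)
    observed = np.bincount(observed_idx, minlength=len(profiles))

    null_counts = np.zeros(len(profiles))
    for perm in perms:
        W = V[:, list(perm)]
        W = W - W[:, :1]
        idx, _ = _assign_matrix(W, profiles)
        null_counts += np.bincount(idx, minlength=len(profiles))
    expected = null_counts / len(perms)

    m = len(profiles)
    results = []
    for i, prof in enumerate(profiles):
        n_obs = int(observed[i])
        n_exp = float(expected[i])
        if n_exp == 0.0:
            # null never reaches this profile; floor documented as 1/(n+1)
            p_raw = 1.0 / (n_genes + 1) if n_obs > 0 else 1.0
        else:
            rate = min(n_exp / n_genes, 1.0)
            p_raw = float(stats.binom.sf(n_obs - 1, n_genes, rate))
        p_adj = min(1.0, p_raw * m)
        results.append(
            ProfileSignificance(prof.id, n_obs, n_exp, p_raw, p_adj, p_adj <= alpha)
        )
    return results


def significant_profiles(results: list[ProfileSignificance]) -> list[int]:
    """IDs of significant profiles, ordered by adjusted p-value ascending."""
    hits = [r for r in results if r.significant]
    hits.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.profile_id))
    return [r.profile_id for r in hits]


# ---- TSV writers -----------------------------------------------------------

def profiles_to_frame(profiles: list[ModelProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.id, ",".join(map(str, p.levels))) for p in profiles],
        columns=["profile", "levels"],
    )


def assignments_to_frame(assignments: list[ProfileAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.gene, a.profile_id, a.distance) for a in assignments],
        columns=["gene", "profile", "distance"],
    )


def significance_to_frame(results: list[ProfileSignificance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.profile_id, r.n_assigned, r.n_expected, r.p_raw, r.p_adjusted, r.significant)
            for r in results
        ],
        columns=["profile", "n_assigned", "n_expected", "p_raw", "p_adjusted", "significant"],
    )
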