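"""Multi-evidence candidate-gene integration.

Combines the three evidence layers of the staged design: genes assigned to
significant temporal model profiles, MCC-filtered hub genes of the DEG
subsets concordant with each profile's pattern, and membership in those DEG
subsets themselves.  Also provides the stagewise hub chi-square contrast
(early- vs advanced-stage hub alteration rates against total DEG counts)
and gene-set enrichment tests (hypergeometric, Fisher, EASE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import SUBSET_LABELS
from .network import HubScore
from .profiles import ModelProfile, ProfileAssignment


def pattern_to_subsets(profile: ModelProfile | tuple[int, ...]) -> set[str]:
    """DEG subset labels concordant with a three-point profile's pattern.

    For levels (0, l1, l2): the sign of l1 sets the MvC direction, the sign
    of l2 the EvC direction, and the sign of l2 - l1 the EvM direction; a
    zero difference contributes no label.
    """
    levels = profile.levels if isinstance(profile, ModelProfile) else tuple(profile)
    if len(levels) != 3:
        raise ValueError("pattern concordance is defined for the 3-point design only")
    _, l1, l2 = levels
    labels = set()
    for diff, comparison in ((l1, "MvC"), (l2, "EvC"), (l2 - l1, "EvM")):
        if diff > 0:
            labels.add(f"{comparison}up")
        elif diff < 0:
            labels.add(f"{comparison}down")
    return labels


def build_subset_networks(
    graph: nx.Graph, subsets: dict[str, set[str]]
) -> dict[str, nx.Graph]:
    """Induced subgraph of the reference interactome per DEG subset."""
    return {label: graph.subgraph(genes).copy() for label, genes in subsets.items()}


@dataclass
class CandidateGene:
    """A gene supported by all three evidence layers (one candidate-table row)."""

    gene: str
    profile_id: int
    subset_scores: list[tuple[str, int]]  # (subset label, MCC) per matched subset
    drmp_p: float | None = None
    drmp_tested: bool = False
    go_terms: int | None = None
    pathways: int | None = None

    @property
    def subsets(self) -> list[str]:
        return [s for s, _ in self.subset_scores]

    @property
    def max_mcc(self) -> int:
        return max(mcc for _, mcc in self.subset_scores)

    @property
    def drmp_significant(self) -> bool:
        return self.drmp_p is not None and self.drmp_p <= 0.05


def intersect_candidates(
    assignments: list[ProfileAssignment],
    significant_ids: list[int],
    profiles: list[ModelProfile],
    hub_scores: dict[str, dict[str, int]],
    deg_sets: dict[str, set[str]],
    min_mcc: int = 10,
    require_all: bool = False,
    hub_sets: dict[str, set[str]] | None = None,
) -> list[CandidateGene]:
    """Intersect profile assignment, hub status and DEG membership.

    A gene assigned to a significant profile P is a candidate iff some DEG
    subset concordant with P's pattern contains it both as a hub (MCC >=
    ``min_mcc``) and as a DEG; with ``require_all`` every concordant subset
    must qualify it.  All matching subsets are recorded with their MCC.

    ``hub_scores`` maps subset label -> node -> MCC within that subset's
    induced network.  Passing explicit ``hub_sets`` cross-checks that every
    hub has a score.
    """
    by_id = {p.id: p for p in profiles}
    if hub_sets is None:
        hub_sets = {
            label: {n for n, mcc in scores.items() if mcc >= min_mcc}
            for label, scores in hub_scores.items()
        }
    else:
        for label, nodes in hub_sets.items():
            missing = nodes - set(hub_scores.get(label, {}))
            if missing:
                raise ValueError(
                    f"hub genes without MCC scores in {label}: {sorted(missing)[:5]}"
                )

    candidates: list[CandidateGene] = []
    sig = set(significant_ids)
    for a in assignments:
        if a.profile_id not in sig:
            continue
        concordant = sorted(
            pattern_to_subsets(by_id[a.profile_id]), key=SUBSET_LABELS.index
        )
        matched = [
            s
            for s in concordant
            if a.gene in hub_sets.get(s, set())
            and hub_scores.get(s, {}).get(a.gene, 0) >= min_mcc
            and a.gene in deg_sets.get(s, set())
        ]
        ok = bool(matched) and (not require_all or len(matched) == len(concordant))
        if ok:
            candidates.append(
                CandidateGene(
                    a.gene,
                    a.profile_id,
                    [(s, int(hub_scores[s][a.gene])) for s in matched],
                )
            )
    return candidates


def scores_as_dict(scores: list[HubScore]) -> dict[str, int]:
    return {s.node: s.mcc for s in scores}


# ---- candidate-table serialization ----------------------------------------

_TABLE_COLUMNS = ["gene", "profile", "mcc_scores", "subsets", "drmp_p"]


def _format_drmp(c: CandidateGene) -> str:
    if c.drmp_p is not None:
        return repr(c.drmp_p) if isinstance(c.drmp_p, float) else str(c.drmp_p)
    return ">0.05" if c.drmp_tested else "NA"


def emit_candidate_table(candidates: list[CandidateGene], path=None) -> pd.DataFrame:
    """Candidate table: rows grouped by profile, sorted by max MCC descending.

    Writes TSV when ``path`` is given.  The MCC column joins per-subset
    scores with commas, ordered to match the subsets column.
    """
    ordered = sorted(candidates, key=lambda c: (c.profile_id, -c.max_mcc, c.gene))
    frame = pd.DataFrame(
        [
            (
                c.gene,
                c.profile_id,
                ",".join(str(m) for _, m in c.subset_scores),
                ",".join(c.subsets),
                _format_drmp(c),
            )
            for c in ordered
        ],
        columns=_TABLE_COLUMNS,
    )
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame


def parse_candidate_table(path) -> list[CandidateGene]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    candidates = []
    for row in frame.itertuples(index=False):
        mccs = [int(x) for x in str(row.mcc_scores).split(",")]
        subsets = str(row.subsets).split(",")
        drmp_raw = str(row.drmp_p)
        if drmp_raw == "NA":
            drmp_p, tested = None, False
        elif drmp_raw.startswith(">"):
            drmp_p, tested = None, True
        else:
            drmp_p, tested = float(drmp_raw), True
        candidates.append(
            CandidateGene(
                str(row.gene),
                int(row.profile),
                list(zip(subsets, mccs)),
                drmp_p=drmp_p,
                drmp_tested=tested,
            )
        )
    return candidates


# ---- stagewise hub chi-square ----------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) / (c, d); here rows are stages, columns hub/total DEGs."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


def stagewise_hub_chisq(
    table: ContingencyTable2x2, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) on a 2x2 table, uncorrected by default.

    Used for the early-vs-advanced contrast of differentially expressed hub
    genes against total DEG counts per comparison.  Continuity correction is
    off by default and available as a flag.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = (a + b, c + d, a + c, b + d)
    if 0 in margins:
        raise ValueError("chi-square undefined: zero marginal total")
    n = a + b + c + d
    delta = abs(a * d - b * c)
    if yates:
        delta = max(delta - n / 2, 0.0)
    chi2 = n * delta**2 / np.prod([float(m) for m in margins])
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---- enrichment -------------------------------------------------------------

def enrichment_test(
    query: set[str],
    annotation: dict[str, set[str]],
    background: set[str],
    method: str = "fisher",
) -> dict[str, float]:
    """Per-term enrichment p-values over a fixed gene background.

    hypergeometric: upper tail P(X >= k) of the overlap; fisher: one-sided
    exact test on the 2x2 query-by-term table; ease: Fisher with the overlap
    reduced by one (floor 0), the conservative variant.
    """
    if not background:
        raise ValueError("empty background")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    N = len(background)
    n = len(query)
    out: dict[str, float] = {}
    for term, genes in annotation.items():
        term_genes = genes & background
        K = len(term_genes)
        k = len(query & term_genes)
        if method == "hypergeometric":
            out[term] = float(stats.hypergeom.sf(k - 1, N, K, n))
        elif method in ("fisher", "ease"):
            if method == "ease":
                k = max(k - 1, 0)
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            out[term] = float(stats.fisher_exact(table, alternative="greater")[1])
        else:
            raise ValueError(f"unknown method {method!r}")
    return out
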