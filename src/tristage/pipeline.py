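"""End-to-end orchestration of the three-evidence integration pipeline.

Chains the module stages: (optional) quantile normalization and detection
filtering, DEG screening over the three pairwise comparisons, temporal
profile assignment with permutation significance, per-subset induced
networks with MCC hub filtering, and the final candidate intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from . import expression as ex
from . import integrate as it
from . import network as net
from . import profiles as pr


@dataclass
class PipelineResult:
    matrix: ex.ExpressionMatrix
    deg_records: list[ex.DEGRecord]
    deg_sets: dict[str, set[str]]
    profiles: list[pr.ModelProfile]
    assignments: list[pr.ProfileAssignment]
    significance: list[pr.ProfileSignificance]
    significant_ids: list[int]
    hub_scores: dict[str, dict[str, int]]
    candidates: list[it.CandidateGene]

    def candidate_genes(self) -> set[str]:
        return {c.gene for c in self.candidates}


def run_pipeline(
    matrix: ex.ExpressionMatrix,
    graph: nx.Graph,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    min_detected: int = 6,
    max_unit_change: int = 2,
    n_profiles: int | None = None,
    alpha: float = 0.05,
    min_mcc: int = 10,
    require_all: bool = False,
    normalize: bool = False,
) -> PipelineResult:
    """Run the full integration on an expression matrix and interactome.

    ``normalize`` applies quantile normalization first; leave it off for
    matrices that are already on a common scale (the synthetic generator's
    output, or pre-normalized platform exports).
    """
    if normalize:
        matrix = ex.quantile_normalize(matrix)
    matrix = ex.detection_filter(matrix, min_detected=min_detected)

    records = ex.screen_all_comparisons(
        matrix, fc_threshold=fc_threshold, p_threshold=p_threshold
    )
    deg_sets = ex.deg_subsets(records)

    vectors = pr.gene_temporal_vector(matrix)
    T = vectors.shape[1]
    candidates_profiles = pr.enumerate_profiles(T, max_unit_change)
    if n_profiles is not None and n_profiles < len(candidates_profiles):
        selected = pr.select_distinct_profiles(candidates_profiles, n_profiles)
    else:
        selected = candidates_profiles
    assignments = pr.assign_genes(vectors, selected)
    significance = pr.permutation_significance(vectors, selected, alpha=alpha)
    significant_ids = pr.significant_profiles(significance)

    subset_graphs = it.build_subset_networks(graph, deg_sets)
    hub_scores = {
        label: it.scores_as_dict(net.mcc_score(g)) for label, g in subset_graphs.items()
    }

    candidates = it.intersect_candidates(
        assignments,
        significant_ids,
        selected,
        hub_scores,
        deg_sets,
        min_mcc=min_mcc,
        require_all=require_all,
    )
    return PipelineResult(
        matrix,
        records,
        deg_sets,
        selected,
        assignments,
        significance,
        significant_ids,
        hub_scores,
        candidates,
    )
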