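"""Packaged candidate-gene and pathway tables (transcribed reference results).

``table1`` is the published 63-row candidate-gene table: per gene its
temporal profile, per-subset MCC scores, GO/pathway annotation counts,
promoter-methylation (DRMP) p-value and hub-gene-set membership.  The
profile ``pattern`` column carries the level pattern inferred from each
profile's subset vocabulary, since profile numbering alone does not encode
the shape.  ``table2`` is the top-five KEGG pathway table over the same
candidates.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .integrate import CandidateGene


def _data_path(name: str):
    return resources.files("tristage.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """The 63-candidate-gene table with profile, MCC, DRMP and subset columns."""
    with resources.as_file(_data_path("table1.tsv")) as path:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("profile", "rank", "go_terms", "pathways"):
        frame[col] = frame[col].astype(int)
    return frame


def load_table2() -> pd.DataFrame:
    """Top five KEGG pathways by number of associated candidate genes."""
    with resources.as_file(_data_path("table2.tsv")) as path:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    frame["rank"] = frame["rank"].astype(int)
    frame["n_genes"] = frame["n_genes"].astype(int)
    return frame


def table1_candidates() -> list[CandidateGene]:
    """Table rows as CandidateGene objects ('>0.05' DRMP cells parse as tested, not significant)."""
    candidates = []
    for row in load_table1().itertuples(index=False):
        mccs = [int(x) for x in row.mcc_scores.split(",")]
        subsets = row.hub_gene_sets.split(",")
        if len(mccs) == 1 and len(subsets) > 1:
            # a single printed score covering multiple subsets
            mccs = mccs * len(subsets)
        drmp_raw = row.drmp_p
        drmp_p = None if drmp_raw.startswith(">") else float(drmp_raw)
        candidates.append(
            CandidateGene(
                row.gene,
                int(row.profile),
                list(zip(subsets, mccs)),
                drmp_p=drmp_p,
                drmp_tested=True,
                go_terms=int(row.go_terms),
                pathways=int(row.pathways),
            )
        )
    return candidates


def table1_patterns() -> dict[int, tuple[int, ...]]:
    """Profile id -> inferred level pattern."""
    frame = load_table1()
    out = {}
    for profile, pattern in zip(frame["profile"], frame["pattern"]):
        out[int(profile)] = tuple(int(x) for x in pattern.split(","))
    return out


def table1_summary() -> dict[str, float]:
    """Bookkeeping counts over the candidate table.

    Totals, per-profile counts, how many candidates carry an M-vs-C or
    E-vs-M subset entry, the fraction visible only outside the E-vs-C
    contrast, and the number with significant promoter methylation.
    """
    candidates = table1_candidates()
    total = len(candidates)
    by_profile: dict[int, int] = {}
    for c in candidates:
        by_profile[c.profile_id] = by_profile.get(c.profile_id, 0) + 1
    has = lambda c, comparison: any(s.startswith(comparison) for s in c.subsets)
    n_mvc = sum(1 for c in candidates if has(c, "MvC"))
    n_evm = sum(1 for c in candidates if has(c, "EvM"))
    n_without_evc = sum(1 for c in candidates if not has(c, "EvC"))
    n_drmp = sum(1 for c in candidates if c.drmp_significant)
    return {
        "total": total,
        "profile_11": by_profile.get(11, 0),
        "mvc_entries": n_mvc,
        "evm_entries": n_evm,
        "without_evc": n_without_evc,
        "without_evc_pct": 100.0 * n_without_evc / total,
        "drmp_significant": n_drmp,
    }
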