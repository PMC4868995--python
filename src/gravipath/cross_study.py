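"""Cross-study comparison of significant pathway tables.

Given per-study bundles of direction-partitioned significant pathways and
their leading-edge genes, this module reports the pathways recurring in at
least ``min_studies`` studies in the same direction (with Venn region counts
over the study combinations) and the pairwise leading-edge gene overlap
between named pathways within a study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

__all__ = [
    "StudyResultBundle",
    "bundle_from_results",
    "overlap_pathways",
    "leading_edge_overlap",
]

Direction = Literal["up", "down"]


@dataclass
class StudyResultBundle:
    """Significant pathways of one study, split by direction of change.

    ``up`` and ``down`` map pathway name -> leading-edge gene list; a
    pathway may appear in at most one direction.
    """

    study_id: str
    up: dict[str, list[str]] = field(default_factory=dict)
    down: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        both = set(self.up) & set(self.down)
        if both:
            raise ValueError(
                f"study {self.study_id!r}: pathways in both directions: "
                f"{sorted(both)}"
            )

    def pathways(self, direction: Direction) -> dict[str, list[str]]:
        if direction == "up":
            return self.up
        if direction == "down":
            return self.down
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")

    def leading_edge(self, pathway: str) -> list[str]:
        if pathway in self.up:
            return self.up[pathway]
        if pathway in self.down:
            return self.down[pathway]
        raise KeyError(pathway)


def bundle_from_results(
    study_id: str,
    results: pd.DataFrame,
    p_max: float = 0.05,
    q_max: float = 1.0,
    nes_min: float = 1.0,
) -> StudyResultBundle:
    """Build a bundle from a GSEA results table.

    The cross-study filter (default p < 0.05 with |NES| >= 1) is
    deliberately independent of the stricter per-study reporting filter.
    """
    sig = results[
        (results["p_nominal"] < p_max)
        & (results["q_fdr"] < q_max)
        & (results["NES"].abs() >= nes_min)
    ]
    up = {
        r.set_name: list(r.leading_edge)
        for r in sig[sig["NES"] > 0].itertuples()
    }
    down = {
        r.set_name: list(r.leading_edge)
        for r in sig[sig["NES"] < 0].itertuples()
    }
    return StudyResultBundle(study_id, up, down)


def overlap_pathways(
    bundles: Sequence[StudyResultBundle],
    min_studies: int,
    direction: Direction,
) -> tuple[dict[str, list[str]], dict[frozenset[str], int]]:
    """Pathways recurring across studies, plus Venn region counts.

    Returns
    -------
    common : dict
        pathway -> sorted list of supporting study ids, for pathways
        significant in the given direction in >= min_studies studies.
    venn : dict
        frozenset of study ids -> number of pathways significant in exactly
        that combination of studies (exclusive Venn regions; regions sum to
        the size of the union of the studies' pathway sets).
    """
    if len(bundles) < 2:
        raise ValueError("at least two study bundles are required")
    if min_studies > len(bundles):
        raise ValueError("min_studies exceeds the number of bundles")
    ids = [b.study_id for b in bundles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate study ids: {ids}")

    support: dict[str, list[str]] = {}
    for b in bundles:
        for pathway in b.pathways(direction):
            support.setdefault(pathway, []).append(b.study_id)

    common = {
        p: sorted(studies)
        for p, studies in support.items()
        if len(studies) >= min_studies
    }
    venn: dict[frozenset[str], int] = {}
    for studies in support.values():
        key = frozenset(studies)
        venn[key] = venn.get(key, 0) + 1
    return common, venn


def leading_edge_overlap(
    bundle: StudyResultBundle, pathway_names: Sequence[str]
) -> pd.DataFrame:
    """Pairwise leading-edge gene overlap between named pathways.

    Returns a table with one row per unordered pair: intersection and union
    sizes and the Jaccard index (0 for two empty leading edges).
    """
    known = sorted(set(bundle.up) | set(bundle.down))
    missing = [p for p in pathway_names if p not in set(known)]
    if missing:
        raise KeyError(
            f"unknown pathways {missing}; valid names: {known}"
        )
    rows = []
    for a, b in combinations(pathway_names, 2):
        ga, gb = set(bundle.leading_edge(a)), set(bundle.leading_edge(b))
        inter, union = len(ga & gb), len(ga | gb)
        rows.append(
            {
                "pathway_a": a,
                "pathway_b": b,
                "intersection": inter,
                "union": union,
                "jaccard": inter / union if union else 0.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["pathway_a", "pathway_b", "intersection", "union", "jaccard"]
    )
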