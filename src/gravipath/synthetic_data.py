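"""Synthetic fixtures with the statistical structure the pipeline assumes.

Three generators cover the pipeline's stages: two-group expression matrices
with planted coordinately shifted gene sets (for the enrichment stage),
block-structured non-negative matrices with planted gene clusters (for the
consensus-NMF stage), and planted-partition PPI edge lists (for the network
stage).  Every generator is fully seeded and returns a truth record so that
recovery can be scored.

Expression values are drawn around a high positive baseline and truncated
at zero, keeping the matrices non-negative by construction (the NMF
positivity precondition); with the default base level 100 and noise sd 10
the truncation is a > 10 sigma event and negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import (
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    PhenotypeLabels,
    PPIEdgeList,
)

__all__ = [
    "SyntheticTruth",
    "generate_gsea_fixture",
    "generate_block_matrix",
    "generate_ppi_fixture",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated fixture."""

    planted_up_sets: dict[str, list[str]] = field(default_factory=dict)
    planted_down_sets: dict[str, list[str]] = field(default_factory=dict)
    effect_size: float = 0.0
    planted_k: int = 0
    block_membership: np.ndarray | None = None
    seed: int | None = None


def generate_gsea_fixture(
    n_genes: int = 2000,
    n_per_group: int = 3,
    n_sets: int = 50,
    set_size: int = 30,
    n_planted: int = 5,
    effect_size: float = 2.0,
    noise_sd: float = 10.0,
    base_level: float = 100.0,
    seed: int | None = None,
    n_planted_down: int = 0,
) -> tuple[ExpressionDataset, PhenotypeLabels, GeneSetCollection, SyntheticTruth]:
    """Two-group expression fixture with planted differential gene sets.

    Background genes are base_level + Normal(0, noise_sd) in both groups
    (truncated at 0); members of a planted up-set additionally receive
    +effect_size * noise_sd in the test group (down-sets mirrored).  Gene
    sets are disjoint blocks of ``set_size`` genes; the first ``n_planted``
    are planted up and the next ``n_planted_down`` down.  Defaults match a
    triplicate two-condition microarray design: 2000 genes, 3 replicates
    per group, 50 sets of 30 with 5 planted at effect size 2.
    """
    if n_planted + n_planted_down > n_sets:
        raise ValueError("more planted sets than sets")
    if n_sets * set_size > n_genes:
        raise ValueError(
            f"{n_sets} disjoint sets of {set_size} genes need more than "
            f"{n_genes} genes"
        )
    if effect_size < 0 or noise_sd <= 0 or n_per_group < 2:
        raise ValueError("invalid effect size, noise sd or replicate count")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes - 1))
    gene_ids = [f"G{i:0{width}d}" for i in range(n_genes)]
    n_samples = 2 * n_per_group
    values = base_level + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))

    sets: list[GeneSet] = []
    truth = SyntheticTruth(effect_size=effect_size, seed=seed)
    test_cols = np.arange(n_per_group)
    for s in range(n_sets):
        members = gene_ids[s * set_size : (s + 1) * set_size]
        rows = np.arange(s * set_size, (s + 1) * set_size)
        if s < n_planted:
            name = f"PLANTED_UP_{s}"
            values[np.ix_(rows, test_cols)] += effect_size * noise_sd
            truth.planted_up_sets[name] = list(members)
        elif s < n_planted + n_planted_down:
            name = f"PLANTED_DOWN_{s}"
            values[np.ix_(rows, test_cols)] -= effect_size * noise_sd
            truth.planted_down_sets[name] = list(members)
        else:
            name = f"NULL_SET_{s}"
        sets.append(GeneSet(name, "synthetic", tuple(members)))

    values = np.maximum(values, 0.0)
    sample_ids = [f"ug_{i}" for i in range(n_per_group)] + [
        f"g1_{i}" for i in range(n_per_group)
    ]
    labels = PhenotypeLabels(
        ["microgravity"] * n_per_group + ["gravity_1g"] * n_per_group,
        ("microgravity", "gravity_1g"),
    )
    dataset = ExpressionDataset(gene_ids, sample_ids, values)
    return dataset, labels, GeneSetCollection(sets, module="synthetic"), truth


def generate_block_matrix(
    n_genes: int = 60,
    n_samples: int = 12,
    k_blocks: int = 3,
    noise_sd: float = 0.1,
    signal_high: float = 10.0,
    signal_low: float = 1.0,
    seed: int | None = None,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Non-negative matrix with ``k_blocks`` planted gene clusters.

    Genes in block b share a distinct positive sample profile (high on
    block b's sample segment, low elsewhere), scaled by a per-gene positive
    amplitude, plus additive Normal(0, noise_sd) noise truncated at zero.
    ``noise_sd`` is on the profile scale, so noise_sd = 0.1 * signal_high
    is 10% of the signal.  With noise_sd = 0 the matrix has exact rank
    k_blocks.
    """
    if k_blocks > min(n_genes, n_samples):
        raise ValueError("k_blocks exceeds the matrix dimensions")
    if k_blocks < 1 or signal_low <= 0 or signal_high <= signal_low:
        raise ValueError("invalid block-signal parameters")
    rng = np.random.default_rng(seed)
    gene_block = np.sort(np.arange(n_genes) % k_blocks)
    sample_block = np.sort(np.arange(n_samples) % k_blocks)
    profiles = np.full((k_blocks, n_samples), signal_low)
    for b in range(k_blocks):
        profiles[b, sample_block == b] = signal_high
    amplitude = rng.uniform(0.5, 1.5, size=n_genes)
    M = amplitude[:, None] * profiles[gene_block]
    if noise_sd > 0:
        M = M + rng.normal(0.0, noise_sd, size=M.shape)
    M = np.maximum(M, 0.0)
    truth = SyntheticTruth(
        planted_k=k_blocks, block_membership=gene_block, seed=seed
    )
    return M, truth


def generate_ppi_fixture(
    truth: SyntheticTruth,
    gene_ids: list[str] | None = None,
    p_within: float = 0.8,
    p_between: float = 0.05,
    seed: int | None = None,
) -> PPIEdgeList:
    """Planted-partition PPI edge list over a block-clustered gene universe.

    Each unordered gene pair receives an edge with probability ``p_within``
    when the genes share a truth block and ``p_between`` otherwise; scores
    are uniform in [0.4, 1.0].
    """
    if truth.block_membership is None:
        raise ValueError("truth carries no block membership")
    if not 0 <= p_between <= p_within <= 1:
        raise ValueError("need 0 <= p_between <= p_within <= 1")
    blocks = np.asarray(truth.block_membership)
    n = blocks.size
    if gene_ids is None:
        width = len(str(n - 1))
        gene_ids = [f"G{i:0{width}d}" for i in range(n)]
    if len(gene_ids) != n:
        raise ValueError("gene_ids length must match block membership")
    rng = np.random.default_rng(seed)
    edges = PPIEdgeList()
    for i in range(n):
        for j in range(i + 1, n):
            p = p_within if blocks[i] == blocks[j] else p_between
            if rng.random() < p:
                edges.add(gene_ids[i], gene_ids[j], rng.uniform(0.4, 1.0))
    return edges
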