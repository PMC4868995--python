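"""Signal-to-noise gene ranking for a two-phenotype design.

The per-gene metric is

    r = (A_test - A_ref) / (sd_test' + sd_ref')

where A is the group mean over biological replicates, sd the sample standard
deviation (n-1 denominator) and sd' = max(sd, sd_floor_fraction * |mean|,
eps) a floored standard deviation that stabilises the ratio for genes with
near-constant replicates.  Setting ``sd_floor_fraction=0`` recovers the bare
metric up to the tiny eps guard.  The test condition is the first declared
phenotype class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataio import ExpressionDataset, PhenotypeLabels

logger = logging.getLogger(__name__)

EPS = 1e-8

__all__ = ["RankedGeneList", "signal_to_noise", "EPS"]


@dataclass
class RankedGeneList:
    """All genes of a dataset ordered by ranking metric, most up-regulated
    first.  ``metric_values`` is non-increasing; ties in the metric are broken
    by lexicographic gene id so that runs are bit-reproducible."""

    gene_ids: list[str]
    metric_values: np.ndarray
    _rank_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.metric_values = np.asarray(self.metric_values, dtype=float)
        if len(self.gene_ids) != self.metric_values.shape[0]:
            raise ValueError("gene_ids and metric_values length mismatch")
        if np.any(np.diff(self.metric_values) > 0):
            raise ValueError("metric_values must be non-increasing")
        self._rank_of = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def rank(self, gene_id: str) -> int:
        """0-based position of a gene in the ranked list."""
        return self._rank_of[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._rank_of


def _group_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return values.mean(axis=1), values.std(axis=1, ddof=1)


def signal_to_noise(
    dataset: ExpressionDataset,
    labels: PhenotypeLabels,
    sd_floor_fraction: float = 0.2,
) -> RankedGeneList:
    """Rank genes by the signal-to-noise metric between the two phenotypes.

    Parameters
    ----------
    dataset, labels
        Expression matrix and matching per-sample class labels; each class
        needs at least 2 replicates.
    sd_floor_fraction
        Fraction of |group mean| used as a lower bound on each group's
        standard deviation (default 0.2).  0 disables the relative floor.

    Returns
    -------
    RankedGeneList sorted by metric descending, ties broken by gene id.
    """
    if labels.n_samples != dataset.n_samples:
        raise ValueError(
            f"dataset has {dataset.n_samples} samples but labels cover "
            f"{labels.n_samples}"
        )
    if sd_floor_fraction < 0:
        raise ValueError("sd_floor_fraction must be >= 0")
    test_cls, ref_cls = labels.class_names
    test = dataset.values[:, labels.indices(test_cls)]
    ref = dataset.values[:, labels.indices(ref_cls)]

    mean_t, sd_t = _group_stats(test)
    mean_r, sd_r = _group_stats(ref)
    sd_t = np.maximum(sd_t, np.maximum(sd_floor_fraction * np.abs(mean_t), EPS))
    sd_r = np.maximum(sd_r, np.maximum(sd_floor_fraction * np.abs(mean_r), EPS))

    num = mean_t - mean_r
    r = num / (sd_t + sd_r)
    degenerate = (num == 0) & (sd_t <= EPS) & (sd_r <= EPS)
    if np.any(degenerate):
        logger.info(
            "%d genes with zero mean difference and zero variance ranked at 0",
            int(degenerate.sum()),
        )
        r = np.where(degenerate, 0.0, r)

    order = sorted(range(dataset.n_genes), key=lambda i: (-r[i], dataset.gene_ids[i]))
    return RankedGeneList([dataset.gene_ids[i] for i in order], r[order])
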