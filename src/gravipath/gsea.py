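"""Weighted Kolmogorov-Smirnov gene-set enrichment with a permutation null.

Walking down a ranked gene list, members of a gene set ("hits") increment a
cumulative hit probability by |r_j|^p / N_R while non-members increment a
miss probability by 1/(N - N_H); the enrichment score (ES) is the deviation
P_hit - P_miss of largest magnitude, signed.  With weight exponent p = 0 the
statistic reduces to the classic two-sample KS D-statistic on ranks; the
default p = 1 weights hits by their ranking metric.

Significance comes from a permutation null (random same-size gene sets by
default, phenotype-label shuffling as an option): a one-sided nominal p with
add-one smoothing, a normalized enrichment score NES = ES / mean |same-sign
null ES|, and an empirical NES-based false-discovery rate q (Benjamini-
Hochberg on nominal p available as an alternative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .dataio import ExpressionDataset, GeneSetCollection, PhenotypeLabels
from .ranking import RankedGeneList, signal_to_noise

logger = logging.getLogger(__name__)

__all__ = [
    "RunningSum",
    "DegenerateSetError",
    "NoOverlapError",
    "enrichment_score",
    "leading_edge",
    "permutation_null",
    "nominal_p",
    "normalize_es",
    "fdr_q",
    "GSEA",
    "run_gsea",
    "filter_significant",
]


class DegenerateSetError(ValueError):
    """Gene set covers the whole ranked list (no misses possible)."""


class NoOverlapError(ValueError):
    """Gene set shares no members with the ranked list."""


@dataclass
class RunningSum:
    """Running-sum trace D_j = P_hit(j) - P_miss(j) for j = 1..N.

    ``peak_index`` is the 1-based list position of the extreme deviation;
    D_0 = 0 is implied and D_N = 0 exactly.
    """

    deviations: np.ndarray
    es: float
    peak_index: int
    n_hits: int
    n_r: float
    p_weight: float


def _hit_mask(rgl: RankedGeneList, gene_set: Iterable[str]) -> np.ndarray:
    mask = np.zeros(rgl.n, dtype=bool)
    for g in gene_set:
        if g in rgl:
            mask[rgl.rank(g)] = True
    return mask


def _hit_weights(abs_w: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-position hit increments (unnormalized); uniform fallback when the
    hit weights sum to zero (all hit metrics exactly 0)."""
    wh = np.where(mask, abs_w, 0.0)
    if wh.sum() == 0.0:
        logger.info("all hit weights are zero; falling back to uniform hits")
        wh = mask.astype(float)
    return wh


def enrichment_score(
    rgl: RankedGeneList, gene_set: Iterable[str], p_weight: float = 1.0
) -> RunningSum:
    """Compute the full running sum of a gene set over a ranked list.

    Raises :class:`NoOverlapError` when no member is present in the list and
    :class:`DegenerateSetError` when every list gene is a member.
    """
    mask = _hit_mask(rgl, gene_set)
    n = rgl.n
    n_hits = int(mask.sum())
    if n_hits == 0:
        raise NoOverlapError("gene set has no members in the ranked list")
    if n_hits == n:
        raise DegenerateSetError("gene set covers the entire ranked list")

    abs_w = np.abs(rgl.metric_values) ** p_weight
    wh = _hit_weights(abs_w, mask)
    cum_hit = np.cumsum(wh)
    n_r = cum_hit[-1]
    p_hit = cum_hit / n_r
    p_miss = np.cumsum(~mask) / float(n - n_hits)
    dev = p_hit - p_miss

    peak = int(np.argmax(np.abs(dev)))
    return RunningSum(
        deviations=dev,
        es=float(dev[peak]),
        peak_index=peak + 1,
        n_hits=n_hits,
        n_r=float(n_r),
        p_weight=p_weight,
    )


def _es_from_hit_ranks(
    abs_w: np.ndarray, hit_ranks: np.ndarray, n: int
) -> float:
    """ES from the sorted 0-based ranks of the hits, without materialising
    the N-long trace.  Matches :func:`enrichment_score` to floating-point
    identity: candidate extremes occur only at hit steps (local maxima) and
    immediately before hits (local minima)."""
    m = hit_ranks.size
    n_miss = n - m
    wh = abs_w[hit_ranks]
    cw = np.cumsum(wh)
    if cw[-1] == 0.0:
        cw = np.arange(1.0, m + 1.0)
    p_hit = cw / cw[-1]
    k = np.arange(m)
    miss_frac = (hit_ranks - k) / float(n_miss)

    d_at_hit = p_hit - miss_frac                       # j = rank+1
    d_before = np.concatenate(([0.0], p_hit[:-1])) - miss_frac  # j = rank
    cand_d = np.concatenate((d_at_hit, d_before))
    cand_j = np.concatenate((hit_ranks + 1, hit_ranks))
    keep = cand_j > 0  # D_0 is not part of the trace
    cand_d, cand_j = cand_d[keep], cand_j[keep]
    best = np.lexsort((cand_j, -np.abs(cand_d)))[0]
    return float(cand_d[best])


def leading_edge(
    run: RunningSum, rgl: RankedGeneList, gene_set: Iterable[str]
) -> list[str]:
    """Gene-set members driving the enrichment, in ranked-list order.

    For positive ES these are the members at list positions up to and
    including the running-sum peak; for negative ES, the members at or after
    the peak.  An exactly zero ES yields an empty leading edge.
    """
    if run.es == 0.0:
        logger.warning("ES is exactly 0; leading edge is empty")
        return []
    members = {g for g in gene_set if g in rgl}
    if run.es > 0:
        return [
            g for g in rgl.gene_ids[: run.peak_index] if g in members
        ]
    return [g for g in rgl.gene_ids[run.peak_index - 1 :] if g in members]


def permutation_null(
    rgl: RankedGeneList,
    set_size: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    p_weight: float = 1.0,
) -> np.ndarray:
    """Null ES distribution from random gene sets of a given size.

    Each of the ``n_perm`` permutations draws ``set_size`` genes without
    replacement from the ranked list's universe and records the set's ES.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = rgl.n
    if set_size >= n:
        raise DegenerateSetError(
            f"set size {set_size} is not below the list length {n}"
        )
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    abs_w = np.abs(rgl.metric_values) ** p_weight
    out = np.empty(n_perm)
    for i in range(n_perm):
        ranks = np.sort(rng.choice(n, size=set_size, replace=False))
        out[i] = _es_from_hit_ranks(abs_w, ranks, n)
    return out


def nominal_p(es: float, null: Sequence[float]) -> float:
    """One-sided permutation p on the sign of the observed ES, with add-one
    smoothing: p = (1 + #{same-sign null at least as extreme}) /
    (1 + #{same-sign null}).

    Restricting the denominator to the same-sign portion of the null keeps
    the p value uniform conditional on the observed sign, so the type-I
    rate matches the nominal level even though the tail is chosen after
    seeing the ES sign.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("at least one null sample is required")
    if es >= 0:
        same = null[null >= 0]
        extreme = int(np.sum(same >= es))
    else:
        same = null[null < 0]
        extreme = int(np.sum(same <= es))
    return (1 + extreme) / (1 + same.size)


def normalize_es(es: float, null: Sequence[float]) -> float:
    """NES = ES / mean(|null ES of the same sign|); NaN when the null holds
    no same-sign samples (such sets are excluded from the FDR)."""
    null = np.asarray(null, dtype=float)
    same = null[null > 0] if es >= 0 else null[null < 0]
    if same.size == 0:
        logger.warning("no same-sign null samples; NES undefined")
        return float("nan")
    return float(es / np.mean(np.abs(same)))


def fdr_q(observed_nes: Sequence[float], null_nes: Sequence[float]) -> np.ndarray:
    """Empirical NES-based FDR q per observed set.

    For a positive NES*, q = [fraction of pooled null NES >= NES*] /
    [fraction of observed NES >= NES*], clipped to [0, 1]; mirrored for
    negative NES.  Monotonicity is enforced along each sign's NES ordering by
    a cumulative minimum from the least extreme end, so a more extreme set
    never reports a larger q.  NaN NES yield NaN q.
    """
    obs = np.asarray(observed_nes, dtype=float)
    null = np.asarray(null_nes, dtype=float)
    null = null[np.isfinite(null)]
    q = np.full(obs.shape, np.nan)
    finite = np.isfinite(obs)
    n_obs = int(finite.sum())
    if n_obs == 0 or null.size == 0:
        return q

    def side(sel: np.ndarray, sign: int) -> None:
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            return
        vals = sign * obs[idx]  # flip so larger = more extreme
        raw = np.empty(idx.size)
        for j, v in enumerate(vals):
            frac_null = np.mean(sign * null >= v)
            frac_obs = np.sum(sign * obs[finite] >= v) / n_obs
            raw[j] = min(1.0, frac_null / frac_obs) if frac_obs > 0 else 1.0
        order = np.argsort(-vals, kind="stable")  # most extreme first
        mono = np.minimum.accumulate(raw[order][::-1])[::-1]
        q[idx[order]] = mono

    side(finite & (obs >= 0), +1)
    side(finite & (obs < 0), -1)
    return q


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "set_name",
    "module",
    "size",
    "ES",
    "NES",
    "p_nominal",
    "q_fdr",
    "peak_index",
    "leading_edge",
]


class GSEA(BaseEstimator):
    """Gene-set enrichment analysis of a two-phenotype expression dataset.

    Parameters
    ----------
    n_perm : int, default 1000
        Number of permutations for the null distribution.
    p_weight : float, default 1.0
        Running-sum weight exponent; 0 gives the unweighted KS statistic.
    min_size, max_size : int
        Gene-set size window after intersection with the ranked list; sets
        outside are skipped with a log entry.
    permutation : {"gene_set", "phenotype"}
        Null scheme: random same-size gene sets (default) or phenotype-label
        shuffling with re-ranking.
    fdr_method : {"gsea", "bh"}
        Empirical NES-based FDR (default) or Benjamini-Hochberg on the
        nominal p values.
    sd_floor_fraction : float, default 0.2
        Standard-deviation floor passed to the signal-to-noise ranking.
    random_state : int or None
        Seed for the permutation null.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per retained gene set, sorted by NES descending, with
        columns ``set_name, module, size, ES, NES, p_nominal, q_fdr,
        peak_index, leading_edge``.
    ranked_list_ : RankedGeneList
        The signal-to-noise ranking the enrichment was computed on.
    """

    def __init__(
        self,
        n_perm: int = 1000,
        p_weight: float = 1.0,
        min_size: int = 15,
        max_size: int = 500,
        permutation: Literal["gene_set", "phenotype"] = "gene_set",
        fdr_method: Literal["gsea", "bh"] = "gsea",
        sd_floor_fraction: float = 0.2,
        random_state: int | None = None,
    ) -> None:
        self.n_perm = n_perm
        self.p_weight = p_weight
        self.min_size = min_size
        self.max_size = max_size
        self.permutation = permutation
        self.fdr_method = fdr_method
        self.sd_floor_fraction = sd_floor_fraction
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _retained_sets(self, rgl: RankedGeneList, collection: GeneSetCollection):
        retained = []
        for gs in collection:
            present = [g for g in gs.genes if g in rgl]
            if not present:
                logger.info("set %r skipped: no overlap with ranked list", gs.name)
                continue
            if not (self.min_size <= len(present) <= self.max_size):
                logger.info(
                    "set %r skipped: size %d outside [%d, %d]",
                    gs.name, len(present), self.min_size, self.max_size,
                )
                continue
            if len(present) >= rgl.n:
                logger.info("set %r skipped: covers the whole list", gs.name)
                continue
            retained.append((gs, present))
        return retained

    def _gene_set_null(self, rgl, retained, rng):
        """One null per distinct effective set size (sizes sorted so the
        seed stream does not depend on collection order)."""
        sizes = sorted({len(present) for _, present in retained})
        return {
            size: permutation_null(
                rgl, size, self.n_perm, rng, p_weight=self.p_weight
            )
            for size in sizes
        }

    def _phenotype_null(self, dataset, labels, retained, rng):
        """Per-set null from phenotype-label shuffling with re-ranking."""
        abs_sets = [set(present) for _, present in retained]
        nulls = np.empty((len(retained), self.n_perm))
        labs = np.array(labels.labels)
        for p in range(self.n_perm):
            perm = PhenotypeLabels(
                list(labs[rng.permutation(labs.size)]), labels.class_names
            )
            rgl_p = signal_to_noise(dataset, perm, self.sd_floor_fraction)
            abs_w = np.abs(rgl_p.metric_values) ** self.p_weight
            for s, members in enumerate(abs_sets):
                ranks = np.sort([rgl_p.rank(g) for g in members])
                nulls[s, p] = _es_from_hit_ranks(
                    abs_w, np.asarray(ranks), rgl_p.n
                )
        return nulls

    # -- API ---------------------------------------------------------------

    def fit(
        self,
        dataset: ExpressionDataset,
        labels: PhenotypeLabels,
        collection: GeneSetCollection,
    ) -> "GSEA":
        """Rank genes, score every retained gene set and attach statistics."""
        rng = np.random.default_rng(self.random_state)
        rgl = signal_to_noise(dataset, labels, self.sd_floor_fraction)
        retained = self._retained_sets(rgl, collection)

        rows = []
        runs = []
        for gs, present in retained:
            run = enrichment_score(rgl, present, self.p_weight)
            runs.append(run)
            rows.append(
                {
                    "set_name": gs.name,
                    "module": collection.module,
                    "size": len(present),
                    "ES": run.es,
                    "peak_index": run.peak_index,
                    "leading_edge": leading_edge(run, rgl, present),
                }
            )

        if retained:
            if self.permutation == "gene_set":
                null_by_size = self._gene_set_null(rgl, retained, rng)
                set_nulls = [
                    null_by_size[len(present)] for _, present in retained
                ]
                pooled_groups = null_by_size.values()
            elif self.permutation == "phenotype":
                nulls = self._phenotype_null(dataset, labels, retained, rng)
                set_nulls = list(nulls)
                pooled_groups = set_nulls
            else:
                raise ValueError(f"unknown permutation scheme {self.permutation!r}")

            for row, run, null in zip(rows, runs, set_nulls):
                row["p_nominal"] = nominal_p(run.es, null)
                row["NES"] = normalize_es(run.es, null)

            obs_nes = np.array([row["NES"] for row in rows])
            if self.fdr_method == "gsea":
                pooled = np.concatenate(
                    [_normalize_null(group) for group in pooled_groups]
                )
                qs = fdr_q(obs_nes, pooled)
            elif self.fdr_method == "bh":
                ps = np.array([row["p_nominal"] for row in rows])
                qs = stats.false_discovery_control(ps, method="bh")
                qs = np.where(np.isfinite(obs_nes), qs, np.nan)
            else:
                raise ValueError(f"unknown fdr method {self.fdr_method!r}")
            for row, q in zip(rows, qs):
                row["q_fdr"] = float(q)

        results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        if len(results):
            results = results.sort_values(
                ["NES", "set_name"], ascending=[False, True], na_position="last"
            ).reset_index(drop=True)
        self.results_ = results
        self.ranked_list_ = rgl
        return self


def _normalize_null(null_es: np.ndarray) -> np.ndarray:
    """Normalize a null ES sample by its own same-sign mean magnitudes,
    producing null NES on the observed NES scale."""
    pos = null_es[null_es > 0]
    neg = null_es[null_es < 0]
    out = np.zeros_like(null_es)
    if pos.size:
        out[null_es > 0] = null_es[null_es > 0] / pos.mean()
    if neg.size:
        out[null_es < 0] = null_es[null_es < 0] / np.abs(neg).mean()
    return out[null_es != 0]


def run_gsea(
    dataset: ExpressionDataset,
    labels: PhenotypeLabels,
    collection: GeneSetCollection,
    **params,
) -> pd.DataFrame:
    """Functional wrapper over :class:`GSEA`; returns the results table."""
    return GSEA(**params).fit(dataset, labels, collection).results_


def filter_significant(
    results: pd.DataFrame, p_max: float = 0.01, q_max: float = 0.25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split significant rows (p_nominal < p_max and q_fdr < q_max) into
    (upregulated NES > 0, downregulated NES < 0) tables."""
    sig = results[
        (results["p_nominal"] < p_max) & (results["q_fdr"] < q_max)
    ]
    up = sig[sig["NES"] > 0].reset_index(drop=True)
    down = sig[sig["NES"] < 0].reset_index(drop=True)
    return up, down
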