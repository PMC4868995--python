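"""End-to-end orchestration: enrichment -> significance filter -> leading-edge
pools -> consensus-NMF clustering -> cluster enrichment / PPI subnetworks ->
cross-study overlap, from one declarative YAML config.

Every stage writes a TSV under the run directory, all randomness derives
from the single config seed, and a manifest records parameters and output
checksums, so re-running the same config reproduces every output
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster_networks import hypergeometric_enrichment, induced_subnetwork
from .consensus_nmf import ConsensusNMF
from .cross_study import bundle_from_results, leading_edge_overlap, overlap_pathways
from .dataio import read_cls, read_edge_list, read_gct, read_gmt
from .gsea import GSEA, filter_significant

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    studies: list[dict[str, str]]
    gene_sets: list[dict[str, str]]
    seed: int = 0
    ppi: str | None = None
    gsea: dict[str, Any] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    nmfc: dict[str, Any] = field(default_factory=dict)
    enrichment: dict[str, Any] = field(default_factory=dict)

    _THRESHOLD_DEFAULTS = {
        "p_max": 0.01,
        "q_max": 0.25,
        "overlap_p_max": 0.05,
        "nes_min": 1.0,
        "min_studies": 3,
    }
    _NMFC_DEFAULTS = {
        "k_min": 2,
        "k_max": 20,
        "n_iter": 2000,
        "n_restarts": 50,
        "drop_threshold": 0.05,
        "min_pool": 12,
    }
    _ENRICH_DEFAULTS = {"p_max": 1e-5, "score_min": 0.4}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            studies=raw["studies"],
            gene_sets=raw["gene_sets"],
            seed=int(raw.get("seed", 0)),
            ppi=raw.get("ppi"),
            gsea=raw.get("gsea", {}),
            thresholds=raw.get("thresholds", {}),
            nmfc=raw.get("nmfc", {}),
            enrichment=raw.get("enrichment", {}),
        )

    def validate(self) -> None:
        """Fail fast: referenced files must exist, thresholds must be sane."""
        if not self.studies:
            raise ValueError("config lists no studies")
        if not self.gene_sets:
            raise ValueError("config lists no gene-set collections")
        ids = [s["id"] for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate study ids: {ids}")
        missing = []
        for s in self.studies:
            for key in ("gct", "cls"):
                if not Path(s[key]).exists():
                    missing.append(s[key])
        for g in self.gene_sets:
            if not Path(g["gmt"]).exists():
                missing.append(g["gmt"])
        if self.ppi is not None and not Path(self.ppi).exists():
            missing.append(self.ppi)
        if missing:
            raise FileNotFoundError(f"config references missing files: {missing}")
        thr = self.resolved_thresholds()
        for key in ("p_max", "q_max", "overlap_p_max"):
            if not 0 < thr[key] <= 1:
                raise ValueError(f"threshold {key} = {thr[key]} outside (0, 1]")
        if thr["min_studies"] < 1:
            raise ValueError("min_studies must be >= 1")

    def resolved_thresholds(self) -> dict[str, float]:
        return {**self._THRESHOLD_DEFAULTS, **self.thresholds}

    def resolved_nmfc(self) -> dict[str, Any]:
        return {**self._NMFC_DEFAULTS, **self.nmfc}

    def resolved_enrichment(self) -> dict[str, Any]:
        return {**self._ENRICH_DEFAULTS, **self.enrichment}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _results_for_io(results: pd.DataFrame) -> pd.DataFrame:
    out = results.copy()
    out["leading_edge"] = out["leading_edge"].map(",".join)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage and return the run directory.

    Outputs per study: ``gsea_<study>.tsv`` (all retained sets),
    ``significant_<study>.tsv``, per-direction leading-edge pools, a
    cophenetic curve, consensus matrices and cluster assignments, a cluster
    pathway-enrichment table and (when a PPI edge list is configured)
    subnetwork summaries.  Across studies: ``common_pathways.tsv``,
    ``venn_counts.tsv`` and ``leading_edge_overlap.tsv``.  A
    ``manifest.json`` records the config, package version and output
    checksums.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gravipath")
    root.addHandler(log_handler)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _run(config: PipelineConfig, outdir: Path) -> Path:
    rng = np.random.default_rng(config.seed)
    thr = config.resolved_thresholds()
    nmfc_params = config.resolved_nmfc()
    enr_params = config.resolved_enrichment()

    collections = [
        read_gmt(g["gmt"], g.get("module", "unlabeled")) for g in config.gene_sets
    ]
    ppi = read_edge_list(config.ppi) if config.ppi else None

    bundles = []
    outputs: list[Path] = []
    for study in config.studies:
        sid = study["id"]
        logger.info("stage gsea: study %s", sid)
        dataset = read_gct(study["gct"])
        labels = read_cls(study["cls"])
        tables = []
        for coll in collections:
            est = GSEA(
                random_state=int(rng.integers(2**31)), **config.gsea
            ).fit(dataset, labels, coll)
            tables.append(est.results_)
        results = pd.concat(tables, ignore_index=True)
        path = outdir / f"gsea_{sid}.tsv"
        _write_tsv(_results_for_io(results), path)
        outputs.append(path)

        up, down = filter_significant(results, thr["p_max"], thr["q_max"])
        sig = pd.concat([up, down], ignore_index=True)
        path = outdir / f"significant_{sid}.tsv"
        _write_tsv(_results_for_io(sig), path)
        outputs.append(path)

        bundles.append(
            bundle_from_results(
                sid, results, thr["overlap_p_max"], nes_min=thr["nes_min"]
            )
        )

        for direction, table in (("up", up), ("down", down)):
            pool: list[str] = []
            for le in table["leading_edge"]:
                for g in le:
                    if g not in pool:
                        pool.append(g)
            path = outdir / f"leading_edge_pool_{sid}_{direction}.tsv"
            _write_tsv(pd.DataFrame({"gene": pool}), path)
            outputs.append(path)
            outputs.extend(
                _nmfc_stage(
                    dataset, pool, sid, direction, nmfc_params, enr_params,
                    collections, ppi, int(rng.integers(2**31)), outdir,
                )
            )

    outputs.extend(_cross_study_stage(bundles, thr, outdir))

    manifest = {
        "package": "gravipath",
        "version": __version__,
        "seed": config.seed,
        "thresholds": thr,
        "gsea": config.gsea,
        "nmfc": nmfc_params,
        "enrichment": enr_params,
        "studies": config.studies,
        "gene_sets": config.gene_sets,
        "ppi": config.ppi,
        "outputs": {
            p.relative_to(outdir).as_posix(): _sha256(p)
            for p in sorted(outputs)
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return outdir


def _nmfc_stage(
    dataset, pool, sid, direction, nmfc_params, enr_params, collections,
    ppi, seed, outdir: Path,
) -> list[Path]:
    """Cluster one study/direction leading-edge pool and annotate clusters."""
    outputs: list[Path] = []
    min_pool = nmfc_params["min_pool"]
    if len(pool) < min_pool:
        logger.info(
            "nmfc skipped for %s/%s: pool of %d genes below %d",
            sid, direction, len(pool), min_pool,
        )
        return outputs
    sub = dataset.subset_genes(pool)
    if not sub.nonnegative:
        raise ValueError(
            f"leading-edge expression for {sid}/{direction} holds negative "
            "values; NMF clustering requires non-negative data"
        )
    logger.info("stage nmfc: %s/%s on %d genes", sid, direction, len(pool))
    est = ConsensusNMF(
        k_min=nmfc_params["k_min"],
        k_max=nmfc_params["k_max"],
        n_iter=nmfc_params["n_iter"],
        n_restarts=nmfc_params["n_restarts"],
        drop_threshold=nmfc_params["drop_threshold"],
        random_state=seed,
    ).fit(sub.values)

    curve = pd.DataFrame(
        {"k": list(est.cophenetic_), "cophenetic": list(est.cophenetic_.values())}
    )
    path = outdir / f"cophenetic_curve_{sid}_{direction}.tsv"
    _write_tsv(curve, path)
    outputs.append(path)

    cons_dir = outdir / f"consensus_{sid}_{direction}"
    cons_dir.mkdir(exist_ok=True)
    for k, C in est.consensus_matrices_.items():
        path = cons_dir / f"consensus_k{k}.tsv"
        pd.DataFrame(C, index=pool, columns=pool).to_csv(
            path, sep="\t", float_format=_FLOAT_FMT
        )
        outputs.append(path)

    clusters = pd.DataFrame({"gene": pool, "cluster": est.labels_})
    path = outdir / f"clusters_{sid}_{direction}.tsv"
    _write_tsv(clusters, path)
    outputs.append(path)

    enrich_tables = []
    subnet_rows = []
    universe = set(dataset.gene_ids)
    for cid in sorted(set(est.labels_)):
        genes = [g for g, c in zip(pool, est.labels_) if c == cid]
        cluster_id = f"{sid}_{direction}_c{cid}"
        for coll in collections:
            enrich_tables.append(
                hypergeometric_enrichment(
                    genes, coll, universe, enr_params["p_max"], cluster_id
                )
            )
        if ppi is not None:
            s = induced_subnetwork(
                genes, ppi, enr_params["score_min"], cluster_id
            )
            subnet_rows.append(
                {
                    "cluster_id": s.cluster_id,
                    "n_nodes": s.n_nodes,
                    "n_edges": s.n_edges,
                    "density": s.density,
                    "component_sizes": ",".join(map(str, s.component_sizes)),
                }
            )
    if enrich_tables:
        path = outdir / f"cluster_enrichment_{sid}_{direction}.tsv"
        _write_tsv(pd.concat(enrich_tables, ignore_index=True), path)
        outputs.append(path)
    if subnet_rows:
        path = outdir / f"subnetworks_{sid}_{direction}.tsv"
        _write_tsv(pd.DataFrame(subnet_rows), path)
        outputs.append(path)
    return outputs


def _cross_study_stage(bundles, thr, outdir: Path) -> list[Path]:
    outputs: list[Path] = []
    if len(bundles) < 2:
        logger.info("cross-study stage skipped: fewer than two studies")
        return outputs
    logger.info("stage cross_study over %d studies", len(bundles))
    min_studies = int(min(thr["min_studies"], len(bundles)))
    common_rows = []
    venn_rows = []
    for direction in ("up", "down"):
        common, venn = overlap_pathways(bundles, min_studies, direction)
        for pathway in sorted(common):
            common_rows.append(
                {
                    "pathway": pathway,
                    "direction": direction,
                    "n_studies": len(common[pathway]),
                    "studies": ",".join(common[pathway]),
                }
            )
        for combo in sorted(venn, key=lambda c: (len(c), tuple(sorted(c)))):
            venn_rows.append(
                {
                    "direction": direction,
                    "studies": ",".join(sorted(combo)),
                    "n_pathways": venn[combo],
                }
            )
    path = outdir / "common_pathways.tsv"
    _write_tsv(
        pd.DataFrame(
            common_rows, columns=["pathway", "direction", "n_studies", "studies"]
        ),
        path,
    )
    outputs.append(path)
    path = outdir / "venn_counts.tsv"
    _write_tsv(
        pd.DataFrame(venn_rows, columns=["direction", "studies", "n_pathways"]),
        path,
    )
    outputs.append(path)

    overlap_rows = []
    common_names = {r["pathway"] for r in common_rows}
    for b in bundles:
        names = sorted(common_names & (set(b.up) | set(b.down)))
        if len(names) >= 2:
            table = leading_edge_overlap(b, names)
            table.insert(0, "study", b.study_id)
            overlap_rows.append(table)
    path = outdir / "leading_edge_overlap.tsv"
    if overlap_rows:
        _write_tsv(pd.concat(overlap_rows, ignore_index=True), path)
    else:
        _write_tsv(
            pd.DataFrame(
                columns=[
                    "study", "pathway_a", "pathway_b",
                    "intersection", "union", "jaccard",
                ]
            ),
            path,
        )
    outputs.append(path)
    return outputs
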