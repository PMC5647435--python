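"""End-to-end pipeline driver.

Stage order follows the analysis contract: QC filters -> kNN imputation ->
differential statistics -> per-dataset variance selection -> combine and
z-scale -> network construction -> module detection -> eigengenes ->
design association -> optional enrichment -> optional recovery evaluation.
Every run writes a resolved-config copy and a manifest of artifact
checksums next to its outputs; identical config + seed reproduces
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as wio
from .module_association import associate_modules, module_eigengenes, overrepresentation
from .network import adjacency, combine_and_scale, detect_modules, pick_soft_power, topological_overlap, variance_select
from .qc_stats import apply_filters, differential_analysis, knn_impute
from .types import DatasetTag, NetworkParams

logger = logging.getLogger("wacna")

__all__ = ["PipelineConfig", "run_pipeline"]

METABOLOME_TAGS = (DatasetTag.METABOLOME_POS, DatasetTag.METABOLOME_NEG)


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths and toggles."""

    # inputs: dataset tag -> matrix TSV path
    matrices: dict = field(default_factory=dict)
    metadata: str = ""
    out_dir: str = "wacna_out"
    seed: int = 0

    # qc_stats
    rsd_threshold: float = 20.0
    min_detection: float = 0.70
    conjunctive_filters: bool = False
    knn_k: int = 3
    diff_factors: tuple = (("diet", "CON", "HFD"), ("exercise", "pre", "post"))
    n_boot: int = 2000

    # network
    top_fraction: float = 0.20
    log_transform_transcriptome: bool = False
    beta: int | str = "auto"  # "auto" -> scale-free criterion
    network_sign: str = "unsigned"
    min_module_size: int = 20
    merge_cut_height: float = 0.25
    deep_split: int = 2
    kme_threshold: float = 0.6

    # association / enrichment / evaluation
    alpha: float = 0.05
    gmt: str | None = None
    ground_truth: str | None = None

    # stage toggles
    run_diffstat: bool = True
    run_enrichment: bool = True
    run_evaluation: bool = True
    write_tom: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.beta, str) and cfg.beta != "auto":
            cfg.beta = int(cfg.beta)
        cfg.diff_factors = tuple(tuple(f) for f in cfg.diff_factors)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["diff_factors"] = [list(f) for f in self.diff_factors]
        return d


def _resolve_matrices(config: PipelineConfig):
    matrices = {}
    for tag, path in config.matrices.items():
        matrices[DatasetTag(tag).value] = wio.read_matrix(path, tag)
    if not matrices:
        raise ValueError("no input matrices configured")
    metadata = wio.read_metadata(config.metadata)
    return matrices, metadata


def run_pipeline(config: PipelineConfig, matrices=None, metadata=None) -> dict:
    """Execute all configured stages; returns a result dict of artifacts.

    ``matrices``/``metadata`` may be passed in-memory (e.g. straight from
    the simulator); otherwise they are read from the configured paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    results: dict = {}
    stage = "setup"
    try:
        if matrices is None or metadata is None:
            stage = "read_inputs"
            matrices, metadata = _resolve_matrices(config)
        # canonical dataset order: replay must not depend on dict ordering
        matrices = {
            t.value: matrices[t.value] for t in DatasetTag if t.value in matrices
        }

        stage = "qc_filters"
        filtered = {}
        for tag, mat in matrices.items():
            if DatasetTag(tag).is_metabolome:
                sub, report = apply_filters(
                    mat,
                    metadata,
                    rsd_threshold=config.rsd_threshold,
                    min_detection=config.min_detection,
                    conjunctive=config.conjunctive_filters,
                )
                artifacts[f"filter_report_{tag}"] = wio.write_filter_report(
                    report, out / f"filter_report_{tag}.tsv"
                )
                logger.info(
                    "qc_filters[%s]: kept %d / %d analytes",
                    tag, len(report.kept_ids), len(report.table),
                )
                filtered[tag] = sub
            else:
                filtered[tag] = mat

        stage = "impute"
        imputed = {}
        for tag, mat in filtered.items():
            imputed[tag] = (
                knn_impute(mat, k=config.knn_k)
                if DatasetTag(tag).is_metabolome
                else mat
            )
        results["imputed"] = imputed

        if config.run_diffstat:
            stage = "diffstat"
            diff = {}
            for tag, mat in imputed.items():
                if not DatasetTag(tag).is_metabolome:
                    continue
                bio = mat.subset_samples(
                    [s for s in mat.sample_ids if s in set(metadata.biological_samples)]
                )
                for factor, lvl_a, lvl_b in config.diff_factors:
                    res = differential_analysis(
                        bio, metadata, (factor, lvl_a), (factor, lvl_b),
                        n_boot=config.n_boot, seed=config.seed,
                    )
                    key = f"diff_{tag}_{factor}_{lvl_a}_vs_{lvl_b}"
                    tbl = res.table.copy()
                    tbl.index.name = "analyte_id"
                    p = out / f"{key}.tsv"
                    tbl.to_csv(p, sep="\t", float_format="%.8g")
                    artifacts[key] = p
                    diff[key] = res
            results["differential"] = diff

        stage = "variance_select"
        selected = {}
        for tag, mat in imputed.items():
            log_tx = (
                config.log_transform_transcriptome
                and not DatasetTag(tag).is_metabolome
            )
            selected[tag] = variance_select(
                mat, metadata, top_fraction=config.top_fraction, log_transform=log_tx
            )
            logger.info("variance_select[%s]: kept %d analytes", tag, selected[tag].n_analytes)

        stage = "combine_and_scale"
        combined = combine_and_scale(selected, metadata)
        results["combined"] = combined

        stage = "network"
        if config.beta == "auto":
            beta, beta_diag = pick_soft_power(
                combined, r2_target=0.80, network_sign=config.network_sign
            )
            beta_diag.to_csv(out / "soft_power_scan.tsv", sep="\t", index=False)
            artifacts["soft_power_scan"] = out / "soft_power_scan.tsv"
        else:
            beta = int(config.beta)
        logger.info("network: beta=%d (%s)", beta, config.network_sign)
        params = NetworkParams(
            beta=beta,
            network_sign=config.network_sign,
            min_module_size=config.min_module_size,
            merge_cut_height=config.merge_cut_height,
            deep_split=config.deep_split,
            kme_threshold=config.kme_threshold,
        )
        adj = adjacency(combined, params.beta, params.network_sign)
        tom = topological_overlap(adj)
        if config.write_tom:
            import pandas as pd

            pd.DataFrame(
                tom, index=combined.analyte_ids, columns=combined.analyte_ids
            ).to_csv(out / "tom.tsv", sep="\t", float_format="%.6g")
            artifacts["tom"] = out / "tom.tsv"

        stage = "detect_modules"
        partition = detect_modules(
            tom, params, analyte_ids=combined.analyte_ids, combined=combined
        )
        artifacts["partition"] = wio.write_partition(partition, out / "module_partition.tsv")
        results["partition"] = partition
        results["beta"] = beta
        logger.info(
            "detect_modules: %d modules, %d grey",
            len(partition.colours),
            int((partition.labels() == "grey").sum()),
        )

        stage = "eigengenes"
        eigengenes = module_eigengenes(combined, partition)
        artifacts["eigengenes"] = wio.write_eigengenes(eigengenes, out / "eigengenes.tsv")
        results["eigengenes"] = eigengenes

        stage = "associate"
        associations = associate_modules(eigengenes, metadata, alpha=config.alpha)
        assoc_tbl = associations.table.copy()
        assoc_tbl.index.name = "module_colour"
        assoc_tbl.to_csv(out / "module_associations.tsv", sep="\t", float_format="%.8g")
        artifacts["associations"] = out / "module_associations.tsv"
        results["associations"] = associations

        if config.run_enrichment and config.gmt:
            stage = "enrichment"
            gene_sets = wio.read_gmt(config.gmt)
            universe = set(combined.analyte_ids)
            import pandas as pd

            frames = []
            for colour in partition.colours:
                enr = overrepresentation(partition.members(colour), gene_sets, universe)
                enr.insert(0, "module_colour", colour)
                frames.append(enr)
            if frames:
                enr_all = pd.concat(frames)
                enr_all.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.8g")
                artifacts["enrichment"] = out / "enrichment.tsv"
                results["enrichment"] = enr_all

        if config.run_evaluation and config.ground_truth:
            stage = "evaluate"
            from .evaluate import recovery_report

            truth = wio.read_ground_truth(config.ground_truth)
            report = recovery_report(truth, partition, eigengenes, associations)
            artifacts["recovery_report"] = wio.write_json(
                report.to_dict(), out / "recovery_report.json"
            )
            results["recovery"] = report

        stage = "manifest"
        resolved = out / "resolved_config.yaml"
        with open(resolved, "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        manifest = {
            name: wio.sha256_file(p) for name, p in sorted(artifacts.items())
        }
        wio.write_json(manifest, out / "manifest.json")
        results["artifacts"] = artifacts
        results["manifest"] = manifest
        return results
    except Exception:
        (out / "FAILED").write_text(f"failed at stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise
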