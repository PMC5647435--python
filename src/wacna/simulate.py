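"""Synthetic paired transcript/metabolite cohort generator.

Plants co-regulated analyte blocks that span all datasets, with additive
diet and exercise effects on the latent block activities, lognormal
intensities, pooled-QC technical replicates (metabolome only) and
detection-limit plus random missingness. Ground truth is returned
separately and is never consumed by the analysis stages.

Randomness layout: the master seed is split with ``SeedSequence.spawn``
into one stream for the shared design/latent draws plus one stream per
dataset, so adding a dataset does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import DatasetTag, OmicsMatrix, SampleMetadata

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort"]

DIET_LEVELS = ("CON", "HFD")
EXERCISE_LEVELS = ("pre", "post")

#: module trait labels
DIET_RESPONSIVE = "diet"
EXERCISE_RESPONSIVE = "exercise"
NEUTRAL = "neutral"

BACKGROUND = "background"


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort (latent scale unless noted)."""

    n_per_group: int = 6
    n_qc: int = 10
    n_transcripts: int = 2000
    n_metabolites_pos: int = 600
    n_metabolites_neg: int = 600
    n_modules: int = 6
    module_size_range: tuple[int, int] = (15, 40)
    diet_effect: float = 2.5
    exercise_effect: float = 2.5
    loading_range: tuple[float, float] = (0.22, 0.32)
    neg_loading_prob: float = 0.0
    noise_sd: float = 0.15
    qc_rsd_range: tuple[float, float] = (2.0, 25.0)  # percent
    detection_quantile: float = 0.05
    mcar_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_per_group": self.n_per_group,
            "n_qc": self.n_qc,
            "n_transcripts": self.n_transcripts,
            "n_metabolites_pos": self.n_metabolites_pos,
            "n_metabolites_neg": self.n_metabolites_neg,
            "n_modules": self.n_modules,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        lo, hi = self.module_size_range
        if not (1 <= lo <= hi):
            raise ValueError("module_size_range must satisfy 1 <= min <= max")
        for nm, n in (
            ("n_transcripts", self.n_transcripts),
            ("n_metabolites_pos", self.n_metabolites_pos),
            ("n_metabolites_neg", self.n_metabolites_neg),
        ):
            if self.n_modules * hi > n:
                raise ValueError(
                    f"n_modules x max module size ({self.n_modules}x{hi}) exceeds {nm}={n}"
                )
        llo, lhi = self.loading_range
        if not (0 < llo <= lhi):
            raise ValueError("loading_range must satisfy 0 < min <= max")
        if not 0 <= self.neg_loading_prob <= 1:
            raise ValueError("neg_loading_prob must be in [0, 1]")
        rlo, rhi = self.qc_rsd_range
        if not (0 <= rlo <= rhi):
            raise ValueError("qc_rsd_range must satisfy 0 <= min <= max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.detection_quantile < 1:
            raise ValueError("detection_quantile must be in [0, 1)")
        if not 0 <= self.mcar_rate < 1:
            raise ValueError("mcar_rate must be in [0, 1)")
        if self.detection_quantile + self.mcar_rate >= 1:
            raise ValueError("detection_quantile + mcar_rate must be < 1")


@dataclass
class GroundTruth:
    """Planted structure for evaluation only.

    ``partition``: DataFrame indexed by analyte id with columns ``dataset``,
    ``module_id`` ("module_<k>" or "background") and ``module_trait``.
    ``module_traits``: module_id -> trait. ``latent_activities``:
    module_id x biological-sample DataFrame.
    """

    partition: pd.DataFrame
    module_traits: dict[str, str] = field(default_factory=dict)
    latent_activities: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: per-dataset target QC RSD draws (percent), metabolome only
    qc_rsd_targets: dict[str, pd.Series] = field(default_factory=dict)

    def module_ids(self) -> list[str]:
        return sorted(self.module_traits)

    def background_ids(self) -> pd.Index:
        return self.partition.index[self.partition["module_id"] == BACKGROUND]


def _module_traits(n_modules: int) -> list[str]:
    """Module 0 is diet-responsive, module 1 exercise-responsive, rest neutral.

    With a single module it responds to diet.
    """
    traits = [NEUTRAL] * n_modules
    traits[0] = DIET_RESPONSIVE
    if n_modules >= 2:
        traits[1] = EXERCISE_RESPONSIVE
    return traits


def _build_metadata(config: SimConfig, rng: np.random.Generator) -> SampleMetadata:
    rows = []
    i = 0
    for diet in DIET_LEVELS:
        for ex in EXERCISE_LEVELS:
            for _ in range(config.n_per_group):
                i += 1
                rows.append((f"S{i:03d}", diet, ex, False))
    for j in range(config.n_qc):
        rows.append((f"QC{j + 1:02d}", "QC", "QC", True))
    tbl = pd.DataFrame(rows, columns=["sample_id", "diet", "exercise", "is_qc"])
    tbl = tbl.set_index("sample_id")
    order = rng.permutation(len(tbl)) + 1
    tbl["run_order"] = order
    return SampleMetadata(tbl)


def _simulate_dataset(
    tag: DatasetTag,
    n_analytes: int,
    prefix: str,
    config: SimConfig,
    activities: np.ndarray,  # n_modules x n_bio
    traits: list[str],
    bio_ids: pd.Index,
    qc_ids: pd.Index,
    rng: np.random.Generator,
) -> tuple[OmicsMatrix, pd.DataFrame, pd.Series | None]:
    n_bio = len(bio_ids)
    n_modules = config.n_modules
    lo, hi = config.module_size_range

    sizes = rng.integers(lo, hi + 1, size=n_modules)
    membership = np.full(n_analytes, -1, dtype=int)  # -1 = background
    pos = 0
    for m, sz in enumerate(sizes):
        membership[pos : pos + sz] = m
        pos += sz
    rng.shuffle(membership)

    llo, lhi = config.loading_range
    signs = np.where(rng.random(n_analytes) < config.neg_loading_prob, -1.0, 1.0)
    loadings = rng.uniform(llo, lhi, size=n_analytes) * signs

    latent = np.empty((n_analytes, n_bio))
    in_module = membership >= 0
    latent[in_module] = (
        loadings[in_module, None] * activities[membership[in_module]]
        + rng.normal(0.0, config.noise_sd, size=(int(in_module.sum()), n_bio))
    )
    # background analytes: independent residual-scale latent noise
    latent[~in_module] = rng.normal(
        0.0, max(config.noise_sd, 1e-12), size=(int((~in_module).sum()), n_bio)
    )

    base = rng.uniform(np.log(1e4), np.log(1e5), size=n_analytes)
    bio = np.exp(latent + base[:, None])

    if tag.is_metabolome:
        # m/z-retention-time pair feature ids, the untargeted LC-MS convention
        mz = rng.uniform(100.0, 1000.0, size=n_analytes)
        rt = rng.uniform(30.0, 720.0, size=n_analytes)
        raw = [f"{prefix}_{m:.4f}_{t:.2f}" for m, t in zip(mz, rt)]
        seen: dict[str, int] = {}
        uniq = []
        for r in raw:
            k = seen.get(r, 0)
            seen[r] = k + 1
            uniq.append(r if k == 0 else f"{r}.{k}")
        ids = pd.Index(uniq, name="analyte_id")
    else:
        ids = pd.Index(
            [f"{prefix}{i + 1:05d}" for i in range(n_analytes)], name="analyte_id"
        )
    values = pd.DataFrame(bio, index=ids, columns=bio_ids)

    target_series = None
    if tag.is_metabolome:
        # pooled QC: biological mean perturbed by per-feature multiplicative
        # lognormal noise whose RSD targets a draw from qc_rsd_range
        target_rsd = rng.uniform(*config.qc_rsd_range, size=n_analytes) / 100.0
        target_series = pd.Series(target_rsd * 100.0, index=ids, name="target_qc_rsd")
        sigma = np.sqrt(np.log1p(target_rsd**2))
        pooled = bio.mean(axis=1)
        qc = pooled[:, None] * np.exp(
            rng.normal(0.0, 1.0, size=(n_analytes, len(qc_ids))) * sigma[:, None]
        )
        qc_df = pd.DataFrame(qc, index=ids, columns=qc_ids)

        # left-censoring at per-feature detection quantile of biological values
        if config.detection_quantile > 0:
            thresh = np.quantile(bio, config.detection_quantile, axis=1)
            values = values.mask(values.lt(thresh, axis=0))
        # additional MCAR on biological entries
        if config.mcar_rate > 0:
            mcar = rng.random(values.shape) < config.mcar_rate
            values = values.mask(pd.DataFrame(mcar, index=ids, columns=bio_ids))
        values = pd.concat([values, qc_df], axis=1)

    truth = pd.DataFrame(
        {
            "dataset": tag.value,
            "module_id": [
                f"module_{m}" if m >= 0 else BACKGROUND for m in membership
            ],
            "module_trait": [
                traits[m] if m >= 0 else BACKGROUND for m in membership
            ],
        },
        index=ids,
    )
    return OmicsMatrix(tag, values), truth, target_series


def simulate_cohort(
    config: SimConfig,
) -> tuple[dict[str, OmicsMatrix], SampleMetadata, GroundTruth]:
    """Generate the full synthetic cohort.

    Returns
    -------
    matrices : dict mapping dataset tag value -> OmicsMatrix
    metadata : SampleMetadata for all samples (QC included)
    truth : GroundTruth (evaluation only; never feed into the pipeline)
    """
    ss = np.random.SeedSequence(config.seed)
    design_rng, *dataset_seeds = ss.spawn(4)
    design_rng = np.random.default_rng(design_rng)

    metadata = _build_metadata(config, design_rng)
    bio_ids = metadata.biological_samples
    qc_ids = metadata.qc_samples
    n_bio = len(bio_ids)

    traits = _module_traits(config.n_modules)
    hfd = metadata.indicator("diet", "HFD", bio_ids).to_numpy()
    post = metadata.indicator("exercise", "post", bio_ids).to_numpy()

    activities = design_rng.normal(0.0, 1.0, size=(config.n_modules, n_bio))
    for m, trait in enumerate(traits):
        if trait == DIET_RESPONSIVE:
            activities[m] += config.diet_effect * hfd
        elif trait == EXERCISE_RESPONSIVE:
            activities[m] += config.exercise_effect * post

    specs = [
        (DatasetTag.TRANSCRIPTOME, config.n_transcripts, "T"),
        (DatasetTag.METABOLOME_POS, config.n_metabolites_pos, "MP"),
        (DatasetTag.METABOLOME_NEG, config.n_metabolites_neg, "MN"),
    ]
    matrices: dict[str, OmicsMatrix] = {}
    truth_parts = []
    rsd_targets: dict[str, pd.Series] = {}
    for (tag, n, prefix), child in zip(specs, dataset_seeds):
        rng = np.random.default_rng(child)
        mat, truth, rsd_target = _simulate_dataset(
            tag, n, prefix, config, activities, traits, bio_ids, qc_ids, rng
        )
        matrices[tag.value] = mat
        truth_parts.append(truth)
        if rsd_target is not None:
            rsd_targets[tag.value] = rsd_target

    partition = pd.concat(truth_parts)
    module_traits = {f"module_{m}": t for m, t in enumerate(traits)}
    latent = pd.DataFrame(
        activities, index=[f"module_{m}" for m in range(config.n_modules)], columns=bio_ids
    )
    return matrices, metadata, GroundTruth(partition, module_traits, latent, rsd_targets)
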