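"""Recovery metrics: how well detected modules match planted structure."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

from .simulate import BACKGROUND, GroundTruth
from .types import GREY, EigengeneTable, ModuleAssociation, ModulePartition

__all__ = ["adjusted_rand", "RecoveryReport", "recovery_report"]


def adjusted_rand(partition_a, partition_b) -> float:
    """Adjusted Rand index from the pair-count contingency table.

    Both arguments map ids to labels (dict or Series); the id sets must
    coincide. Returns 1.0 for two one-cluster (or two all-singleton)
    partitions, where the expected-index denominator degenerates.
    """
    a = pd.Series(partition_a)
    b = pd.Series(partition_b)
    if set(a.index) != set(b.index):
        raise ValueError("partitions cover different id sets")
    b = b.reindex(a.index)
    _, ai = np.unique(a.to_numpy(), return_inverse=True)
    _, bi = np.unique(b.to_numpy(), return_inverse=True)
    nb = bi.max() + 1
    ct = np.bincount(ai * nb + bi, minlength=(ai.max() + 1) * nb).reshape(-1, nb)
    n = ct.sum()
    sum_ij = comb(ct, 2).sum()
    sum_a = comb(ct.sum(axis=1), 2).sum()
    sum_b = comb(ct.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


@dataclass
class RecoveryReport:
    """Planted-structure recovery summary.

    ari: adjusted Rand index between detected and planted module labels
    (grey/background excluded by default); module_purity: per-module max
    fraction from one planted module, size-weighted mean; trait accuracy:
    fraction of flagged modules whose dominant planted trait matches the
    flagged factor; eigengene fidelity: mean |cor| between each module
    eigengene and its dominant planted module's latent activity;
    background_rejection: fraction of planted-background analytes in the
    partition labelled grey.
    """

    ari: float
    module_purity: float
    trait_assignment_accuracy: float
    eigengene_fidelity: float
    background_rejection: float
    n_detected_modules: int
    n_flagged_modules: int

    def to_dict(self) -> dict:
        return asdict(self)


def _dominant_planted(members: pd.Index, truth_labels: pd.Series) -> tuple[str, float]:
    labels = truth_labels.reindex(members).dropna()
    if labels.empty:
        return BACKGROUND, 0.0
    counts = labels.value_counts()
    return str(counts.index[0]), float(counts.iloc[0] / len(labels))


def recovery_report(
    truth: GroundTruth,
    partition: ModulePartition,
    eigengenes: EigengeneTable | None = None,
    associations: ModuleAssociation | None = None,
    include_background: bool = False,
) -> RecoveryReport:
    """Score a detected partition (and optional eigengenes/associations)
    against the planted ground truth."""
    detected = partition.labels()
    truth_labels = truth.partition["module_id"].reindex(detected.index)
    if truth_labels.isna().any():
        missing = detected.index[truth_labels.isna()].tolist()
        raise ValueError(f"analytes absent from ground truth: {missing[:5]}")

    if include_background:
        keep = detected.index
    else:
        keep = detected.index[(detected != GREY) & (truth_labels != BACKGROUND)]
    if len(keep) >= 2:
        ari = adjusted_rand(detected.loc[keep], truth_labels.loc[keep])
    else:
        ari = np.nan

    colours = partition.colours
    purities, weights = [], []
    dominant: dict[str, str] = {}
    for colour in colours:
        members = partition.members(colour)
        dom, purity = _dominant_planted(members, truth_labels)
        dominant[colour] = dom
        purities.append(purity)
        weights.append(len(members))
    module_purity = (
        float(np.average(purities, weights=weights)) if purities else np.nan
    )

    bg = truth_labels.index[truth_labels == BACKGROUND]
    background_rejection = (
        float((detected.loc[bg] == GREY).mean()) if len(bg) else 1.0
    )

    eigengene_fidelity = np.nan
    if eigengenes is not None and colours:
        cors = []
        for colour in colours:
            dom = dominant[colour]
            if dom == BACKGROUND or dom not in truth.latent_activities.index:
                continue
            eig = eigengenes.values.loc[colour]
            act = truth.latent_activities.loc[dom].reindex(eig.index)
            if act.isna().any():
                continue
            cors.append(abs(float(np.corrcoef(eig, act)[0, 1])))
        if cors:
            eigengene_fidelity = float(np.mean(cors))

    trait_acc = 1.0
    n_flagged = 0
    if associations is not None:
        tbl = associations.table
        flagged = [c for c in tbl.index[tbl["flagged_of_interest"]] if c in dominant]
        n_flagged = len(flagged)
        if flagged:
            hits = 0
            for colour in flagged:
                factors = set()
                if tbl.loc[colour, "diet_q"] < associations.alpha:
                    factors.add("diet")
                if tbl.loc[colour, "exercise_q"] < associations.alpha:
                    factors.add("exercise")
                trait = truth.module_traits.get(dominant[colour], BACKGROUND)
                if trait in factors:
                    hits += 1
            trait_acc = hits / len(flagged)

    return RecoveryReport(
        ari=float(ari),
        module_purity=module_purity,
        trait_assignment_accuracy=float(trait_acc),
        eigengene_fidelity=float(eigengene_fidelity),
        background_rejection=background_rejection,
        n_detected_modules=len(colours),
        n_flagged_modules=n_flagged,
    )
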