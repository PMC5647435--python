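"""Metabolomics feature QC filters, kNN imputation and univariate statistics.

Filtering removes features whose pooled-QC relative standard deviation
exceeds 20% or that are detected in fewer than 70% of biological samples
(two independent removal criteria; a conjunctive reading is available via
``conjunctive=True`` on :func:`apply_filters`). Missing values in retained
features are imputed with analyte-space k-nearest-neighbour imputation
(k = 3 by default). Group comparisons use the two-sided
Wilcoxon-Mann-Whitney test with Benjamini-Hochberg FDR adjustment, and
fold changes carry 95% percentile-bootstrap confidence limits.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import DatasetTag, DifferentialResult, FilterReport, OmicsMatrix, SampleMetadata

__all__ = [
    "qc_rsd_filter",
    "detection_filter",
    "apply_filters",
    "knn_impute",
    "wilcoxon_mw",
    "bh_adjust",
    "fold_change",
    "differential_analysis",
    "class_rollup",
]


# ---------------------------------------------------------------------------
# filters


def qc_rsd_filter(
    matrix: OmicsMatrix, metadata: SampleMetadata, threshold: float = 20.0
) -> FilterReport:
    """Flag analytes whose QC-replicate RSD exceeds ``threshold`` percent.

    RSD = 100 * sample SD / mean over non-missing QC values. Analytes with
    no observed QC value are removed (reason "rsd"). Transcriptome input has
    no QC concept: everything passes with a warning.
    """
    if not matrix.dataset_tag.is_metabolome:
        warnings.warn(
            f"QC RSD filter is a no-op for {matrix.dataset_tag.value}", stacklevel=2
        )
        tbl = pd.DataFrame(
            {
                "qc_rsd": np.nan,
                "detection_fraction": np.nan,
                "kept": True,
                "removal_reason": "none",
            },
            index=matrix.analyte_ids,
        )
        return FilterReport(matrix.dataset_tag, tbl)

    qc_cols = [s for s in matrix.sample_ids if s in set(metadata.qc_samples)]
    if len(qc_cols) < 2:
        raise ValueError(
            f"QC RSD filter needs >= 2 QC samples; found {len(qc_cols)} "
            f"in {matrix.dataset_tag.value}"
        )
    qc = matrix.values[qc_cols]
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    rsd = 100.0 * sd / mean
    all_missing = qc.isna().all(axis=1)
    removed = (rsd > threshold) | all_missing
    rsd = rsd.where(~all_missing)
    tbl = pd.DataFrame(
        {
            "qc_rsd": rsd,
            "detection_fraction": np.nan,
            "kept": ~removed,
            "removal_reason": np.where(removed, "rsd", "none"),
        },
        index=matrix.analyte_ids,
    )
    return FilterReport(matrix.dataset_tag, tbl)


def detection_filter(
    matrix: OmicsMatrix, metadata: SampleMetadata, min_detection: float = 0.70
) -> FilterReport:
    """Flag analytes detected in fewer than ``min_detection`` of biological samples."""
    bio_cols = [s for s in matrix.sample_ids if s in set(metadata.biological_samples)]
    if not bio_cols:
        raise ValueError("no biological samples in matrix")
    frac = matrix.values[bio_cols].notna().mean(axis=1)
    removed = frac < min_detection
    tbl = pd.DataFrame(
        {
            "qc_rsd": np.nan,
            "detection_fraction": frac,
            "kept": ~removed,
            "removal_reason": np.where(removed, "detection", "none"),
        },
        index=matrix.analyte_ids,
    )
    return FilterReport(matrix.dataset_tag, tbl)


def apply_filters(
    matrix: OmicsMatrix,
    metadata: SampleMetadata,
    rsd_threshold: float = 20.0,
    min_detection: float = 0.70,
    conjunctive: bool = False,
) -> tuple[OmicsMatrix, FilterReport]:
    """Run both filters and subset the matrix to kept analytes.

    Default: removal if (RSD > threshold) OR (detection < min_detection).
    ``conjunctive=True`` removes only analytes failing both criteria.
    """
    if not matrix.dataset_tag.is_metabolome:
        rep = qc_rsd_filter(matrix, metadata)  # pass-through with warning
        return matrix, rep
    rsd_rep = qc_rsd_filter(matrix, metadata, rsd_threshold)
    det_rep = detection_filter(matrix, metadata, min_detection)
    tbl = pd.DataFrame(
        {
            "qc_rsd": rsd_rep.table["qc_rsd"],
            "detection_fraction": det_rep.table["detection_fraction"],
        },
        index=matrix.analyte_ids,
    )
    fail_rsd = ~rsd_rep.table["kept"]
    fail_det = ~det_rep.table["kept"]
    removed = (fail_rsd & fail_det) if conjunctive else (fail_rsd | fail_det)
    tbl["kept"] = ~removed
    tbl["removal_reason"] = np.where(
        ~removed, "none", np.where(fail_rsd, "rsd", "detection")
    )
    report = FilterReport(matrix.dataset_tag, tbl)
    return matrix.subset_analytes(report.kept_ids), report


# ---------------------------------------------------------------------------
# kNN imputation


def knn_impute(matrix: OmicsMatrix, k: int = 3) -> OmicsMatrix:
    """Analyte-space kNN imputation (classical expression-matrix convention).

    For each missing entry (analyte a, sample s): among analytes observed at
    s, the k nearest to a — Euclidean distance over samples where both are
    observed — contribute their values at s as an unweighted mean. Fewer than
    k eligible neighbours: fall back to all eligible with a warning; none:
    impute the analyte's own observed mean with a warning. Observed entries
    are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = matrix.values.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    if obs.all():
        return matrix
    if (~obs).all(axis=1).any():
        bad = matrix.analyte_ids[(~obs).all(axis=1)].tolist()
        raise ValueError(f"analytes with no observed value cannot be imputed: {bad}")

    x0 = np.where(obs, vals, 0.0)
    m = obs.astype(float)
    sq = x0**2
    # D2[i,j] = sum over co-observed samples of (x_i - x_j)^2
    d2 = sq @ m.T + m @ sq.T - 2.0 * (x0 @ x0.T)
    d2 = np.maximum(d2, 0.0)
    co_obs = m @ m.T
    d2[co_obs == 0] = np.inf
    np.fill_diagonal(d2, np.inf)

    out = vals.copy()
    short_fallback = mean_fallback = 0
    row_means = np.array([vals[i, obs[i]].mean() for i in range(vals.shape[0])])
    for i, s in zip(*np.where(~obs)):
        eligible = np.where(obs[:, s] & np.isfinite(d2[i]))[0]
        if eligible.size == 0:
            out[i, s] = row_means[i]
            mean_fallback += 1
            continue
        if eligible.size < k:
            short_fallback += 1
            chosen = eligible
        else:
            order = np.argsort(d2[i, eligible], kind="stable")
            chosen = eligible[order[:k]]
        donors = vals[chosen, s]
        # exact when donors agree (mean of equal floats can drift an ulp)
        out[i, s] = donors[0] if (donors == donors[0]).all() else donors.mean()
    if short_fallback:
        warnings.warn(
            f"{short_fallback} missing entries had fewer than k={k} eligible "
            "neighbours; used all eligible",
            stacklevel=2,
        )
    if mean_fallback:
        warnings.warn(
            f"{mean_fallback} missing entries had no eligible neighbour; "
            "imputed the analyte's observed mean",
            stacklevel=2,
        )
    return OmicsMatrix(
        matrix.dataset_tag,
        pd.DataFrame(out, index=matrix.analyte_ids, columns=matrix.sample_ids),
    )


# ---------------------------------------------------------------------------
# univariate statistics


def _mwu_p(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def wilcoxon_mw(
    matrix: OmicsMatrix,
    metadata: SampleMetadata,
    group_a,
    group_b,
) -> pd.Series:
    """Two-sided Wilcoxon-Mann-Whitney p-value per analyte.

    ``group_a``/``group_b`` are either (factor, level) tuples or explicit
    sample-id lists. Exact null distribution for combined n <= 12 without
    ties, midrank normal approximation with tie correction otherwise.
    """
    sa = _resolve_group(metadata, group_a)
    sb = _resolve_group(metadata, group_b)
    sa = [s for s in sa if s in set(matrix.sample_ids)]
    sb = [s for s in sb if s in set(matrix.sample_ids)]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(f"each group needs >= 2 samples (got {len(sa)}, {len(sb)})")
    va = matrix.values[sa].to_numpy(dtype=float)
    vb = matrix.values[sb].to_numpy(dtype=float)
    if np.isnan(va).any() or np.isnan(vb).any():
        raise ValueError("wilcoxon_mw requires a complete (post-imputation) matrix")
    p = np.array([_mwu_p(va[i], vb[i]) for i in range(va.shape[0])])
    return pd.Series(p, index=matrix.analyte_ids, name="p_raw")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    # q >= p holds mathematically; guard against float round-down at m/j ~ 1
    return np.maximum(q, p)


def _resolve_group(metadata: SampleMetadata, group) -> list[str]:
    if isinstance(group, tuple) and len(group) == 2 and isinstance(group[0], str):
        factor, level = group
        return list(metadata.group_samples(factor, level))
    return list(group)


def fold_change(
    matrix: OmicsMatrix,
    metadata: SampleMetadata,
    group_a,
    group_b,
    ci_level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Signed fold change of group means with percentile-bootstrap CI.

    Ratio = mean_b / mean_a; reported as the ratio when >= 1, else as
    -1/ratio, so |fold_change| >= 1 always and the sign gives direction.
    CI bounds are mapped through the same (monotone) sign convention.
    """
    sa = _resolve_group(metadata, group_a)
    sb = _resolve_group(metadata, group_b)
    va = matrix.values[sa].to_numpy(dtype=float)
    vb = matrix.values[sb].to_numpy(dtype=float)
    if np.isnan(va).any() or np.isnan(vb).any():
        raise ValueError("fold_change requires a complete (post-imputation) matrix")
    ma, mb = va.mean(axis=1), vb.mean(axis=1)
    if (ma == 0).any() or (mb == 0).any():
        raise ValueError("zero group mean: cannot form an intensity ratio")

    rng = np.random.default_rng(seed)
    na, nb = va.shape[1], vb.shape[1]
    ia = rng.integers(0, na, size=(n_boot, na))
    ib = rng.integers(0, nb, size=(n_boot, nb))
    # orientation: ratio = mean_b / mean_a
    boot_ratio = vb[:, ib].mean(axis=2) / va[:, ia].mean(axis=2)
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    ci = np.quantile(boot_ratio, [lo_q, hi_q], axis=1)
    ratio = mb / ma
    ci_lo = np.minimum(ci[0], ratio)
    ci_hi = np.maximum(ci[1], ratio)

    def signed(r: np.ndarray) -> np.ndarray:
        return np.where(r >= 1.0, r, -1.0 / r)

    tbl = pd.DataFrame(
        {
            "fold_change": signed(ratio),
            "ci_low": signed(ci_lo),
            "ci_high": signed(ci_hi),
            "ratio": ratio,
            "ratio_ci_low": ci_lo,
            "ratio_ci_high": ci_hi,
        },
        index=matrix.analyte_ids,
    )
    return tbl


def differential_analysis(
    matrix: OmicsMatrix,
    metadata: SampleMetadata,
    group_a,
    group_b,
    ci_level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> DifferentialResult:
    """Full per-analyte comparison: fold change + CI, Wilcoxon p, BH q."""
    fc = fold_change(matrix, metadata, group_a, group_b, ci_level, n_boot, seed)
    p = wilcoxon_mw(matrix, metadata, group_a, group_b)
    tbl = fc[["fold_change", "ci_low", "ci_high"]].copy()
    tbl["p_raw"] = p
    tbl["q_bh"] = bh_adjust(p.to_numpy())
    tbl["direction"] = np.where(tbl["fold_change"] >= 1.0, "up", "down")
    name_a = group_a[1] if isinstance(group_a, tuple) else "group_a"
    name_b = group_b[1] if isinstance(group_b, tuple) else "group_b"
    return DifferentialResult(name_a, name_b, tbl)


def class_rollup(
    result: DifferentialResult,
    annotation: pd.Series | dict,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-class counts/percentages of significant analytes by direction.

    ``annotation`` maps analyte id -> class label; unannotated analytes roll
    up under "unknown". Percentages are of the total significant analytes in
    the same direction.
    """
    ann = pd.Series(annotation, dtype=object) if isinstance(annotation, dict) else annotation
    sig = result.significant(q_threshold)
    rows = []
    for direction in ("up", "down"):
        sub = sig[sig["direction"] == direction]
        total = len(sub)
        if total == 0:
            continue
        classes = ann.reindex(sub.index).fillna("unknown")
        counts = classes.value_counts()
        for cls, n in counts.items():
            rows.append(
                {
                    "direction": direction,
                    "class": cls,
                    "count": int(n),
                    "percent": 100.0 * n / total,
                }
            )
    return pd.DataFrame(rows, columns=["direction", "class", "count", "percent"])
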