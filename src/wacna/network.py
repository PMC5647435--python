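"""Weighted correlation network core.

Per-dataset variance selection, concatenation + z-scaling, soft-thresholded
adjacency, topological overlap, and module detection by average-linkage
clustering of the TOM dissimilarity with an adaptive branch cut and
eigengene-based module merging. Unsigned Pearson networks are the default;
the signed variant is available via :class:`~wacna.types.NetworkParams`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .types import GREY, CombinedMatrix, ModulePartition, NetworkParams, OmicsMatrix, SampleMetadata

__all__ = [
    "variance_select",
    "combine_and_scale",
    "pick_soft_power",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "MODULE_COLOURS",
]

# standard WGCNA colour sequence (decreasing module size order)
MODULE_COLOURS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


def variance_select(
    matrix: OmicsMatrix,
    metadata: SampleMetadata | None = None,
    top_fraction: float = 0.20,
    log_transform: bool = False,
) -> OmicsMatrix:
    """Keep the ceil(top_fraction * n) analytes with largest sample variance.

    Variance is computed over biological samples only (QC columns, if any,
    are dropped from the output as well). Ties break lexicographically by
    analyte id. ``log_transform`` applies log2(x+1) first (off by default).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    mat = matrix
    if metadata is not None:
        bio = [s for s in mat.sample_ids if s in set(metadata.biological_samples)]
        mat = mat.subset_samples(bio)
    vals = mat.values
    if vals.isna().any().any():
        raise ValueError("variance_select requires a complete (imputed) matrix")
    if log_transform:
        vals = np.log2(vals + 1.0)
    n_keep = int(np.ceil(top_fraction * len(vals)))
    if n_keep < 2:
        raise ValueError(
            f"top_fraction={top_fraction} keeps {n_keep} analyte(s); need >= 2"
        )
    var = vals.var(axis=1, ddof=1)
    ranking = pd.DataFrame({"var": var, "id": var.index}).sort_values(
        ["var", "id"], ascending=[False, True], kind="stable"
    )
    keep = ranking.index[:n_keep]
    out = mat.subset_analytes(keep)
    if log_transform:
        out.values.loc[:, :] = np.log2(out.values + 1.0)
    return out


def combine_and_scale(
    matrices: dict[str, OmicsMatrix] | list[OmicsMatrix],
    metadata: SampleMetadata,
) -> CombinedMatrix:
    """Row-concatenate datasets and standardise each analyte to mean 0 / SD 1.

    All datasets must cover the identical biological sample set; QC columns
    are dropped. Zero-variance analytes are rejected.
    """
    mats = list(matrices.values()) if isinstance(matrices, dict) else list(matrices)
    if not mats:
        raise ValueError("no matrices to combine")
    bio = set(metadata.biological_samples)
    sample_sets = [frozenset(s for s in m.sample_ids if s in bio) for m in mats]
    common = sample_sets[0]
    for m, ss in zip(mats, sample_sets[1:]):
        if ss != common:
            diff = sorted(common.symmetric_difference(ss))
            raise ValueError(f"biological sample sets differ between datasets: {diff}")
    # stable sample order: metadata order restricted to the common set
    samples = [s for s in metadata.biological_samples if s in common]

    blocks, tags = [], []
    for m in mats:
        block = m.values[samples]
        if block.isna().any().any():
            raise ValueError(f"{m.dataset_tag.value} contains missing values; impute first")
        blocks.append(block)
        tags.extend([m.dataset_tag.value] * len(block))
    stacked = pd.concat(blocks, axis=0)
    if stacked.index.duplicated().any():
        raise ValueError("analyte ids collide across datasets")
    arr = stacked.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = stacked.index[sd == 0].tolist()
        raise ValueError(f"zero-variance analytes cannot be scaled: {bad[:5]}")
    scaled = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    values = pd.DataFrame(scaled, index=stacked.index, columns=samples)
    return CombinedMatrix(values, pd.Series(tags, index=stacked.index, name="dataset"))


def adjacency(
    combined: CombinedMatrix | pd.DataFrame | np.ndarray,
    beta: int,
    network_sign: str = "unsigned",
) -> np.ndarray:
    """Soft-thresholded correlation adjacency.

    unsigned: a_ij = |cor|^beta; signed: a_ij = ((1+cor)/2)^beta. The
    diagonal is stored as 1 but excluded from connectivity sums downstream.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if isinstance(combined, CombinedMatrix):
        x = combined.values.to_numpy(dtype=float)
    elif isinstance(combined, pd.DataFrame):
        x = combined.to_numpy(dtype=float)
    else:
        x = np.asarray(combined, dtype=float)
    cor = np.corrcoef(x)
    cor = np.clip(cor, -1.0, 1.0)
    if network_sign == "unsigned":
        a = np.abs(cor) ** beta
    elif network_sign == "signed":
        a = ((1.0 + cor) / 2.0) ** beta
    else:
        raise ValueError("network_sign must be 'unsigned' or 'signed'")
    np.fill_diagonal(a, 1.0)
    return a


def connectivity(adj: np.ndarray) -> np.ndarray:
    """Node connectivity k_i = sum_{j != i} a_ij."""
    return adj.sum(axis=1) - np.diag(adj)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) vs log10 k over equal-width connectivity bins.

    Positive when the slope is negative (scale-free decay); the sign
    adjustment penalises increasing degree distributions.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float) / k.size
    centers = np.array([k[which == b].mean() if (which == b).any() else np.nan
                        for b in range(n_bins)])
    ok = (freq > 0) & np.isfinite(centers) & (centers > 0)
    if ok.sum() < 3:
        return np.nan
    lx, ly = np.log10(centers[ok]), np.log10(freq[ok])
    slope, _ = np.polyfit(lx, ly, 1)
    r = np.corrcoef(lx, ly)[0, 1]
    return -np.sign(slope) * r**2


def pick_soft_power(
    combined: CombinedMatrix,
    candidate_betas=range(1, 21),
    r2_target: float = 0.80,
    network_sign: str = "unsigned",
) -> tuple[int, pd.DataFrame]:
    """Smallest beta whose scale-free fit R^2 reaches ``r2_target``.

    Falls back to the argmax-R^2 beta with a warning when no candidate
    reaches the target; degenerate (constant-connectivity) networks return
    the conventional default beta = 6 with a warning. Also returns the
    per-candidate diagnostic table (beta, r_squared, mean_k).
    """
    if len(combined.analyte_ids) < 10:
        raise ValueError("need >= 10 analytes to assess scale-free fit")
    rows = []
    for beta in candidate_betas:
        a = adjacency(combined, int(beta), network_sign)
        k = connectivity(a)
        if np.ptp(k) < 1e-12:
            warnings.warn(
                "degenerate connectivity (all nodes equal); returning default beta=6",
                stacklevel=2,
            )
            diag = pd.DataFrame({"beta": [beta], "r_squared": [np.nan], "mean_k": [k.mean()]})
            return 6, diag
        rows.append({"beta": int(beta), "r_squared": scale_free_fit(k), "mean_k": k.mean()})
    diag = pd.DataFrame(rows)
    hit = diag[diag["r_squared"] >= r2_target]
    if len(hit):
        return int(hit["beta"].iloc[0]), diag
    best = int(diag.loc[diag["r_squared"].idxmax(), "beta"])
    warnings.warn(
        f"no candidate beta reached scale-free R^2 >= {r2_target}; "
        f"using argmax beta={best}",
        stacklevel=2,
    )
    return best, diag


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = (a + a.T) / 2.0
    a_off = a.copy()
    np.fill_diagonal(a_off, 0.0)
    k = a_off.sum(axis=1)
    # L_ij over u != i,j: subtract the u=i and u=j terms of the full product
    l_full = a_off @ a_off
    l = l_full  # diagonal terms a_ii are already zeroed in a_off
    k_min = np.minimum.outer(k, k)
    denom = k_min + 1.0 - a_off
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a_off) / denom
    tom = np.where(denom <= 0, 0.0, tom)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _cut_height(heights: np.ndarray, deep_split: int) -> float | None:
    """Adaptive branch-cut height via the largest merge-height gap.

    Module-internal merges happen low in the dendrogram; merges joining
    unrelated branches (background noise, module-module joins) concentrate
    near the top. The cut is placed in the middle of the largest gap between
    consecutive sorted merge heights, searched above a deep-split-dependent
    quantile (deeper split = wider search = finer modules). Returns None when
    the dendrogram is height-degenerate (no structure).
    """
    h = np.sort(heights)
    if h.size < 2 or np.ptp(h) < 1e-8:
        return None
    lo_q = [0.90, 0.75, 0.50, 0.25, 0.10][deep_split]
    floor = np.quantile(h, lo_q)
    idx = np.where(h >= floor)[0]
    start = max(int(idx[0]), 1)
    gaps = h[start:] - h[start - 1 : -1]
    if gaps.size == 0 or gaps.max() < 1e-8:
        return None
    g = int(np.argmax(gaps)) + start
    return float((h[g] + h[g - 1]) / 2.0)


def _label_partition(
    ids: pd.Index, assignments: dict, dataset_of: pd.Series | None
) -> ModulePartition:
    """Colour modules by decreasing size (ties: smallest member id)."""
    groups: dict[int, list] = {}
    for aid, g in assignments.items():
        groups.setdefault(g, []).append(aid)
    ordered = sorted(
        (g for g in groups if g >= 0),
        key=lambda g: (-len(groups[g]), min(groups[g])),
    )
    colour_of_group = {}
    for i, g in enumerate(ordered):
        colour_of_group[g] = (
            MODULE_COLOURS[i] if i < len(MODULE_COLOURS) else f"module{i + 1}"
        )
    colours = [
        colour_of_group.get(assignments[aid], GREY) if assignments[aid] >= 0 else GREY
        for aid in ids
    ]
    tbl = pd.DataFrame({"module_colour": colours}, index=ids)
    tbl.insert(
        0,
        "dataset",
        dataset_of.reindex(ids) if dataset_of is not None else "unknown",
    )
    return ModulePartition(tbl)


def detect_modules(
    tom: np.ndarray,
    params: NetworkParams,
    analyte_ids=None,
    combined: CombinedMatrix | None = None,
) -> ModulePartition:
    """Module detection on the TOM dissimilarity.

    Average-linkage hierarchical clustering of d = 1 - TOM, branches below an
    adaptive cut height (controlled by ``deep_split``) of size >=
    ``min_module_size`` become modules; everything else is grey. When
    ``combined`` is given, modules whose eigengene correlation exceeds
    1 - merge_cut_height are merged iteratively. Modules are named by the
    standard colour sequence in decreasing size order.
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if analyte_ids is None:
        analyte_ids = pd.Index([f"node{i}" for i in range(n)])
    else:
        analyte_ids = pd.Index(analyte_ids)
    if len(analyte_ids) != n:
        raise ValueError("analyte_ids length does not match TOM")
    dataset_of = combined.dataset_of if combined is not None else None

    if n < params.min_module_size:
        warnings.warn("fewer analytes than min_module_size; all grey", stacklevel=2)
        return _label_partition(analyte_ids, {a: -1 for a in analyte_ids}, dataset_of)

    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    cut = _cut_height(link[:, 2], params.deep_split)
    if cut is None:
        warnings.warn("degenerate dendrogram (no height structure); all grey", stacklevel=2)
        return _label_partition(analyte_ids, {a: -1 for a in analyte_ids}, dataset_of)
    flat = hierarchy.fcluster(link, t=cut, criterion="distance")

    sizes = pd.Series(flat).value_counts()
    module_clusters = sizes.index[sizes >= params.min_module_size]
    grp = {c: i for i, c in enumerate(module_clusters)}
    assignments = {
        aid: grp.get(c, -1) for aid, c in zip(analyte_ids, flat)
    }

    if combined is not None and params.merge_cut_height > 0:
        assignments = _merge_by_eigengene(assignments, combined, params.merge_cut_height)
    if combined is not None and params.kme_threshold > 0:
        assignments = _kme_purge(
            assignments, combined, params.kme_threshold, params.min_module_size
        )

    return _label_partition(analyte_ids, assignments, dataset_of)


def _kme_purge(
    assignments: dict, combined: CombinedMatrix, threshold: float, min_size: int
) -> dict:
    """Grey out analytes weakly correlated with their module eigengene.

    Modules that fall below ``min_size`` after the purge dissolve to grey.
    """
    from .module_association import _first_pc  # local import: avoid cycle

    x = combined.values
    out = dict(assignments)
    for g in sorted({g for g in assignments.values() if g >= 0}):
        members = [a for a, gg in assignments.items() if gg == g]
        sub = x.loc[members].to_numpy()
        eig = _first_pc(sub)[0]
        e0 = eig - eig.mean()
        denom = np.linalg.norm(e0)
        for aid, row in zip(members, sub):
            r0 = row - row.mean()
            nr = np.linalg.norm(r0)
            kme = abs(float(r0 @ e0) / (nr * denom)) if nr > 0 and denom > 0 else 0.0
            if kme < threshold:
                out[aid] = -1
        if sum(1 for a in members if out[a] == g) < min_size:
            for a in members:
                out[a] = -1
    return out


def _merge_by_eigengene(
    assignments: dict, combined: CombinedMatrix, merge_cut_height: float, max_iter: int = 5
) -> dict:
    """Merge module groups whose eigengenes correlate above 1 - merge_cut_height."""
    from .module_association import _first_pc  # local import: avoid cycle

    x = combined.values
    for _ in range(max_iter):
        groups = sorted({g for g in assignments.values() if g >= 0})
        if len(groups) < 2:
            return assignments
        eig = {}
        for g in groups:
            members = [a for a, gg in assignments.items() if gg == g]
            sub = x.loc[[a for a in members if a in x.index]]
            if len(sub) == 0:
                continue
            eig[g] = _first_pc(sub.to_numpy())[0]
        groups = sorted(eig)
        e = np.vstack([eig[g] for g in groups])
        cor = np.corrcoef(e)
        d = 1.0 - cor
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        if len(groups) == 2:
            flat = np.array([1, 1]) if d[0, 1] < merge_cut_height else np.array([1, 2])
        else:
            elink = hierarchy.linkage(squareform(d, checks=False), method="average")
            flat = hierarchy.fcluster(elink, t=merge_cut_height, criterion="distance")
        remap = {g: f for g, f in zip(groups, flat)}
        if len(set(remap.values())) == len(groups):
            return assignments
        assignments = {
            a: (remap[g] if g >= 0 else -1) for a, g in assignments.items()
        }
    return assignments
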