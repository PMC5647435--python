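"""Module eigengenes, design-factor association, and over-representation.

The eigengene of a module is the first principal component of its
member x sample submatrix (sample scores), oriented so that it correlates
positively with the module's mean analyte profile. Modules are associated
with the diet and exercise factors by indicator correlation plus a
two-factor fixed-effects decomposition for the interaction; BH adjustment
runs across modules within each factor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .qc_stats import bh_adjust
from .types import (
    GREY,
    CombinedMatrix,
    EigengeneTable,
    ModuleAssociation,
    ModulePartition,
    SampleMetadata,
)

__all__ = ["module_eigengenes", "associate_modules", "overrepresentation"]


def _first_pc(x: np.ndarray) -> tuple[np.ndarray, float]:
    """First right singular vector (unit-norm sample scores) of the
    row-centred analyte x sample matrix, and its variance-explained share."""
    xc = x - x.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = (s**2).sum()
    ve = float(s[0] ** 2 / total) if total > 0 else 0.0
    return vt[0], ve


def module_eigengenes(
    combined: CombinedMatrix, partition: ModulePartition
) -> EigengeneTable:
    """Per-module first-PC sample scores and variance-explained fractions.

    Grey analytes are excluded; a size-1 module's eigengene is that
    analyte's profile scaled to unit norm (with a warning). Orientation:
    positive correlation with the module's mean analyte profile.
    """
    missing = partition.analyte_ids.difference(combined.analyte_ids)
    if len(missing):
        raise ValueError(
            f"partition covers analytes absent from combined matrix: {list(missing[:5])}"
        )
    rows, ve = {}, {}
    for colour in partition.colours:
        members = partition.members(colour)
        sub = combined.values.loc[members].to_numpy(dtype=float)
        if len(members) == 1:
            warnings.warn(f"module {colour} has a single analyte", stacklevel=2)
        pc, frac = _first_pc(sub)
        mean_profile = sub.mean(axis=0)
        orient = np.corrcoef(pc, mean_profile)[0, 1] if np.ptp(mean_profile) > 0 else 1.0
        if orient < 0:
            pc = -pc
        rows[colour] = pc
        ve[colour] = frac
    values = pd.DataFrame(rows, index=combined.sample_ids).T
    values.index.name = "module_colour"
    return EigengeneTable(values, pd.Series(ve, name="variance_explained"))


def _indicator_cor(eig: np.ndarray, indicator: np.ndarray) -> tuple[float, float]:
    if np.ptp(indicator) == 0 or np.ptp(eig) == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(eig, indicator)
    return float(r), float(p)


def _interaction_p(eig: np.ndarray, hfd: np.ndarray, post: np.ndarray) -> float:
    """Interaction p from the 2x2 fixed-effects linear decomposition."""
    import statsmodels.api as sm

    x = np.column_stack([np.ones_like(hfd), hfd, post, hfd * post])
    if np.linalg.matrix_rank(x) < 4:
        return np.nan
    fit = sm.OLS(eig, x).fit()
    return float(fit.pvalues[3])


def associate_modules(
    eigengenes: EigengeneTable,
    metadata: SampleMetadata,
    alpha: float = 0.05,
) -> ModuleAssociation:
    """Correlate each eigengene with the diet/exercise indicators.

    BH adjustment across modules within each factor; a module is flagged of
    interest when either factor's q-value falls below ``alpha``.
    """
    samples = [s for s in eigengenes.sample_ids if s in set(metadata.biological_samples)]
    tbl = metadata.table.loc[samples]
    cells = tbl.groupby(["diet", "exercise"], observed=True).size()
    if len(cells) < 2:
        raise ValueError("design has a single cell; association is undefined")
    if (cells < 2).any():
        raise ValueError("each design cell needs >= 2 samples")
    hfd = (tbl["diet"] == "HFD").to_numpy(float)
    post = (tbl["exercise"] == "post").to_numpy(float)

    rows = []
    for colour in eigengenes.module_colours:
        eig = eigengenes.values.loc[colour, samples].to_numpy(float)
        d_r, d_p = _indicator_cor(eig, hfd)
        e_r, e_p = _indicator_cor(eig, post)
        rows.append(
            {
                "module_colour": colour,
                "diet_cor": d_r,
                "diet_p": d_p,
                "exercise_cor": e_r,
                "exercise_p": e_p,
                "interaction_p": _interaction_p(eig, hfd, post),
            }
        )
    out = pd.DataFrame(rows).set_index("module_colour")
    if len(out):
        out["diet_q"] = bh_adjust(out["diet_p"].to_numpy())
        out["exercise_q"] = bh_adjust(out["exercise_p"].to_numpy())
        out["flagged_of_interest"] = (out["diet_q"] < alpha) | (out["exercise_q"] < alpha)
    else:
        out["diet_q"] = out["exercise_q"] = pd.Series(dtype=float)
        out["flagged_of_interest"] = pd.Series(dtype=bool)
    return ModuleAssociation(out, alpha)


def overrepresentation(
    module_members,
    gene_sets: dict[str, set | list],
    universe,
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation of ``module_members``
    in each named set, BH-adjusted across sets.

    Sets are intersected with the universe; the module must be a subset of
    the universe. Returns a frame indexed by set name with columns
    overlap, set_size, module_size, universe_size, p_hyper, q_bh,
    overlap_ids.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_members)
    if not module <= universe:
        extra = sorted(module - universe)
        raise ValueError(f"module members outside universe: {extra[:5]}")
    n_u, n_m = len(universe), len(module)
    rows = []
    for name, members in gene_sets.items():
        s = set(members) & universe
        overlap = sorted(module & s)
        # P(X >= overlap) for X ~ Hypergeom(N=n_u, K=|s|, n=n_m)
        p = float(stats.hypergeom.sf(len(overlap) - 1, n_u, len(s), n_m))
        rows.append(
            {
                "set_name": name,
                "overlap": len(overlap),
                "set_size": len(s),
                "module_size": n_m,
                "universe_size": n_u,
                "p_hyper": min(p, 1.0),
                "overlap_ids": ";".join(map(str, overlap)),
            }
        )
    out = pd.DataFrame(rows).set_index("set_name")
    if len(out):
        out["q_bh"] = bh_adjust(out["p_hyper"].to_numpy())
    else:
        out["q_bh"] = pd.Series(dtype=float)
    return out[["overlap", "set_size", "module_size", "universe_size", "p_hyper", "q_bh", "overlap_ids"]]
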