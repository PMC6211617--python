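"""Cross-species atlas comparison and per-slice ASE prediction.

Quantitative expression atlases give one expression value per nucleus per
gene for each species.  To compare them: each gene is background-corrected
against the inter-stripe region (55-75% egg length) and scaled by the 90th
percentile of the remaining nuclei; nuclei are then matched across atlases
(among the 30 physically closest, the one with the most similar expression
over a chosen gene set); per-nucleus bias and per-bin "virtual slice" ASE
follow the ASE score formula applied to matched expression values,

    ASE_pred(bin) = (sum f_sim - sum f_mel) / (sum f_sim + sum f_mel)

summed over the nuclei of each 4%-of-egg-length bin.  Nuclei or bins with
expression below 20% of the peak in both species carry no callable bias.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .containers import ASEMatrix, NucleusAtlas

__all__ = [
    "normalize_atlas_gene",
    "match_nuclei",
    "nucleus_bias",
    "predicted_slice_ase",
    "bin_observed_ase",
    "correlate_predicted",
]


def normalize_atlas_gene(
    atlas: NucleusAtlas,
    gene: str,
    interstripe: tuple[float, float] = (0.55, 0.75),
    percentile: float = 0.90,
) -> pd.Series:
    """Background-correct and scale one gene's atlas expression.

    Subtracts the mean expression of nuclei in the inter-stripe interval
    (x fractions), then divides by the value at the given percentile of
    the centered expression outside that interval.  Negative values are
    permitted (background-subtracted).
    """
    if gene not in atlas.data.columns:
        raise KeyError(f"gene {gene!r} not in atlas")
    xf = atlas.x_fraction()
    inter = (xf >= interstripe[0]) & (xf <= interstripe[1])
    if not inter.any() or inter.all():
        raise ValueError("inter-stripe region and its complement must both be non-empty")
    v = atlas.data[gene].astype(float)
    centered = v - v[inter].mean()
    q = float(np.quantile(centered[~inter], percentile))
    if q <= 0:
        raise ValueError(f"gene {gene!r} not normalizable: percentile value {q} <= 0")
    return centered / q


def match_nuclei(
    atlas_a: NucleusAtlas,
    atlas_b: NucleusAtlas,
    genes: list[str],
    k: int = 30,
) -> pd.Series:
    """Match each nucleus of ``atlas_a`` to its best counterpart in ``atlas_b``.

    Among the ``k`` physically closest b-nuclei (Euclidean distance in x,
    y, z) the match minimizes the summed squared expression difference
    over ``genes``; ties break by physical distance, then by nucleus id.
    Both atlases should already hold normalized expression in ``genes``.

    Returns a Series mapping a-nucleus ids to b-nucleus ids.
    """
    if not genes:
        raise ValueError("gene list for matching must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, len(atlas_b.data))
    tree = cKDTree(atlas_b.positions())
    dists, idx = tree.query(atlas_a.positions(), k=k)
    if k == 1:
        dists = dists[:, None]
        idx = idx[:, None]

    expr_a = atlas_a.data[genes].to_numpy(dtype=float)
    expr_b = atlas_b.data[genes].to_numpy(dtype=float)
    b_ids = atlas_b.data.index.to_numpy()

    matches = []
    for i in range(expr_a.shape[0]):
        cand = idx[i]
        sse = np.sum((expr_b[cand] - expr_a[i]) ** 2, axis=1)
        # deterministic tie-break: expression SSE, then distance, then id
        order = np.lexsort((b_ids[cand], dists[i], sse))
        matches.append(b_ids[cand[order[0]]])
    return pd.Series(matches, index=atlas_a.data.index, name="matched_nucleus")


def nucleus_bias(f_mel, f_sim, peak: float, min_frac: float = 0.2):
    """Per-nucleus allelic bias from matched expression values.

    Negative (background-subtracted) expression is clipped to 0 before the
    ratio; nuclei whose larger expression value is below ``min_frac`` of
    the gene's peak carry no callable bias (NaN).  Accepts scalars or
    aligned arrays.
    """
    if peak <= 0:
        raise ValueError("peak expression must be positive")
    fm = np.asarray(f_mel, dtype=float)
    fs = np.asarray(f_sim, dtype=float)
    callable_ = np.maximum(fm, fs) >= min_frac * peak
    fm = np.clip(fm, 0.0, None)
    fs = np.clip(fs, 0.0, None)
    total = fm + fs
    with np.errstate(invalid="ignore", divide="ignore"):
        bias = np.where(callable_ & (total > 0), (fs - fm) / np.where(total > 0, total, 1.0), np.nan)
    return float(bias) if bias.ndim == 0 else bias


def predicted_slice_ase(
    x_frac,
    f_mel,
    f_sim,
    bin_width: float = 0.04,
    min_frac: float = 0.2,
) -> pd.DataFrame:
    """Predicted ASE of virtual slices from matched per-nucleus expression.

    Nuclei are grouped into bins of ``bin_width`` egg-length fractions;
    within each bin both species' (clipped) expression is summed and the
    ASE score computed.  Bins where the per-nucleus mean of the stronger
    species stays below ``min_frac`` of the gene's peak are missing.

    Returns a DataFrame indexed by bin index with ``x_center, ase,
    n_nuclei``.
    """
    xf = np.asarray(x_frac, dtype=float)
    fm = np.clip(np.asarray(f_mel, dtype=float), 0.0, None)
    fs = np.clip(np.asarray(f_sim, dtype=float), 0.0, None)
    if not (xf.size == fm.size == fs.size):
        raise ValueError("x_frac, f_mel and f_sim must be aligned")
    peak = float(np.max(np.maximum(fm, fs), initial=0.0))
    if peak <= 0:
        raise ValueError("gene has no positive expression in either atlas")

    n_bins = int(np.ceil(1.0 / bin_width))
    which = np.minimum((xf / bin_width).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        n = int(sel.sum())
        sm = fm[sel].sum()
        ss = fs[sel].sum()
        callable_ = n > 0 and max(sm, ss) / n >= min_frac * peak and (sm + ss) > 0
        rows.append(
            {
                "x_center": (b + 0.5) * bin_width,
                "ase": (ss - sm) / (ss + sm) if callable_ else np.nan,
                "n_nuclei": n,
            }
        )
    return pd.DataFrame(rows)


def bin_observed_ase(matrix: ASEMatrix, gene: str, bin_width: float = 0.04) -> pd.DataFrame:
    """Bin a gene's observed per-slice ASE onto the predicted-ASE bin grid.

    Slices from all embryos are pooled and averaged within each bin of
    ``bin_width`` egg-length fractions.
    """
    x, y = matrix.gene_profile(gene)
    n_bins = int(np.ceil(1.0 / bin_width))
    which = np.minimum((x / bin_width).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        rows.append(
            {
                "x_center": (b + 0.5) * bin_width,
                "ase": float(y[sel].mean()) if sel.any() else np.nan,
                "n_slices": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def correlate_predicted(predicted, observed, min_bins: int = 3) -> float:
    """Pearson correlation of predicted and observed ASE over joint bins."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.size != o.size:
        raise ValueError("predicted and observed must be on the same bin grid")
    keep = np.isfinite(p) & np.isfinite(o)
    if keep.sum() < min_bins:
        raise ValueError(f"only {int(keep.sum())} jointly callable bins (need >= {min_bins})")
    return float(pearsonr(p[keep], o[keep])[0])
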