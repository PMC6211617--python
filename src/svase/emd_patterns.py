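"""Expression-pattern normalization and earth-mover-distance tests.

Absolute expression profiles along the anterior-posterior axis are turned
into unit-mass patterns (pseudocount, then divide by the total), and
differences between patterns are measured with the 1-D earth mover
distance: the minimal mass-times-distance transport cost, which for
fixed-length 1-D histograms equals the summed absolute difference of the
two cumulative distributions (one distance unit per slice).

Two hypothesis tests are provided:

* hybrid mis-expression — are hybrid embryos farther from the averaged
  parental reference pattern than the two parents are from each other?
  (one-sample, one-sided t-test per gene on the hybrid-to-reference EMDs)
* cross-direction differences — are hybrids with different mothers more
  different from each other than replicates sharing a mother?
  (two-sample, one-sided t-test on pairwise EMDs)

Both are Benjamini-Hochberg corrected across genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionPattern",
    "normalize_pattern",
    "emd_1d",
    "resample_pattern",
    "parental_average_pattern",
    "parental_reference",
    "hybrid_misexpression_test",
    "cross_direction_test",
]


@dataclass(frozen=True)
class ExpressionPattern:
    """A unit-mass expression pattern over the slices of one embryo."""

    weights: tuple[float, ...]
    gene_id: str = ""
    embryo_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size == 0:
            raise ValueError("pattern must have at least one slice")
        if np.any(w < -1e-12):
            raise ValueError("pattern weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"pattern weights must sum to 1 (got {w.sum()!r})")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    def __len__(self) -> int:
        return len(self.weights)


def normalize_pattern(
    expression: Sequence[float],
    pseudocount: float = 1.0,
    gene_id: str = "",
    embryo_id: str = "",
) -> ExpressionPattern:
    """Normalize per-slice expression to a unit-mass pattern.

    Adds ``pseudocount`` to every slice (damping noise in lowly expressed
    genes) and divides by the total.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    v = np.asarray(expression, dtype=float)
    if v.size == 0:
        raise ValueError("expression must have at least one slice")
    if np.any(v < 0):
        raise ValueError("expression values must be non-negative")
    v = v + pseudocount
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero expression with pseudocount 0 cannot be normalized")
    return ExpressionPattern(
        weights=tuple(v / total), gene_id=gene_id, embryo_id=embryo_id
    )


def _as_weights(p) -> np.ndarray:
    if isinstance(p, ExpressionPattern):
        return p.as_array()
    return np.asarray(p, dtype=float)


def emd_1d(p, q) -> float:
    """1-D earth mover distance between equal-length unit-mass patterns.

    Equals ``sum_i |CDF_p(i) - CDF_q(i)|`` with a ground distance of one
    unit per slice — the optimal-transport cost on the line.
    """
    pw = _as_weights(p)
    qw = _as_weights(q)
    if pw.size != qw.size:
        raise ValueError(
            f"patterns have different lengths ({pw.size} vs {qw.size}); "
            "resample to a common slice count first"
        )
    return float(np.abs(np.cumsum(pw) - np.cumsum(qw)).sum())


def _rolling_mean3(v: np.ndarray) -> np.ndarray:
    return pd.Series(v).rolling(3, center=True, min_periods=1).mean().to_numpy()


def _fit_spline(x: np.ndarray, y: np.ndarray) -> UnivariateSpline:
    """Cubic smoothing spline with the smoothing factor chosen by LOOCV.

    The candidate smoothing factors span interpolation to heavy smoothing,
    scaled by the profile's total variation; leave-one-out prediction error
    picks among them.
    """
    n = x.size
    scale = max(float(np.sum((y - y.mean()) ** 2)), 1e-12)
    s_grid = [0.0, 0.01 * scale, 0.03 * scale, 0.1 * scale, 0.3 * scale]
    best_s, best_err = s_grid[0], np.inf
    if n >= 6:
        for s in s_grid:
            err = 0.0
            for i in range(n):
                keep = np.ones(n, dtype=bool)
                keep[i] = False
                try:
                    sp = UnivariateSpline(x[keep], y[keep], k=3, s=s)
                except Exception:
                    err = np.inf
                    break
                err += float((sp(x[i]) - y[i]) ** 2)
            if err < best_err:
                best_err, best_s = err, s
    return UnivariateSpline(x, y, k=3, s=best_s)


def resample_pattern(expression: Sequence[float], n_out: int) -> np.ndarray:
    """Smooth one embryo's profile and predict it on an ``n_out``-slice axis.

    Rolling mean of 3 slices, cubic smoothing spline on per-embryo
    normalized x, evaluation at the ``n_out`` slice midpoints; negative
    predictions clipped to 0.
    """
    v = np.asarray(expression, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 slices to resample a profile")
    x = (np.arange(1, v.size + 1) - 0.5) / v.size
    smoothed = _rolling_mean3(v)
    spline = _fit_spline(x, smoothed)
    x_out = (np.arange(1, n_out + 1) - 0.5) / n_out
    pred = np.clip(spline(x_out), 0.0, None)
    return pred


def parental_average_pattern(
    mel_expression: Sequence[float],
    sim_expression: Sequence[float],
    n_out: int = 27,
    gene_id: str = "",
) -> ExpressionPattern:
    """Averaged parental reference pattern on a hypothetical n_out-slice embryo.

    Each parent's profile is smoothed, spline-resampled to ``n_out``
    slices and normalized to unit mass; the two are averaged and
    renormalized.
    """
    preds = []
    for v in (mel_expression, sim_expression):
        pred = resample_pattern(v, n_out)
        total = pred.sum()
        if total <= 0:
            raise ValueError("a parental profile resampled to zero mass")
        preds.append(pred / total)
    avg = (preds[0] + preds[1]) / 2.0
    avg = avg / avg.sum()
    return ExpressionPattern(weights=tuple(avg), gene_id=gene_id, embryo_id="parental_avg")


def parental_reference(
    mel_expression: Sequence[float],
    sim_expression: Sequence[float],
    n_out: int = 27,
    gene_id: str = "",
) -> tuple[ExpressionPattern, float]:
    """Averaged parental pattern plus the EMD between the two parents."""
    resampled = []
    for v in (mel_expression, sim_expression):
        pred = resample_pattern(v, n_out)
        total = pred.sum()
        if total <= 0:
            raise ValueError("a parental profile resampled to zero mass")
        resampled.append(pred / total)
    avg = (resampled[0] + resampled[1]) / 2.0
    pattern = ExpressionPattern(weights=tuple(avg / avg.sum()), gene_id=gene_id,
                                embryo_id="parental_avg")
    return pattern, float(np.abs(np.cumsum(resampled[0]) - np.cumsum(resampled[1])).sum())


def _one_sided_one_sample(values: np.ndarray, popmean: float) -> tuple[float, float]:
    """t-test of mean(values) > popmean; zero-variance input gives p = 1."""
    if np.std(values, ddof=1) == 0:
        return 0.0, 1.0
    res = stats.ttest_1samp(values, popmean, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def hybrid_misexpression_test(
    hybrid_patterns: Mapping[str, Sequence[ExpressionPattern]],
    parental_avg: Mapping[str, ExpressionPattern],
    parental_emd: Mapping[str, float],
) -> pd.DataFrame:
    """Per gene: are hybrids farther from the parental average than the parents?

    For each gene the EMD of every hybrid embryo to the parental reference
    is tested (one-sample, one-sided t) against the parent-parent EMD; BH
    correction across genes.

    Returns a DataFrame indexed by gene with ``statistic, p_value,
    q_value, mean_hybrid_emd, parental_emd``.
    """
    rows = []
    for gene, patterns in hybrid_patterns.items():
        if len(patterns) < 2:
            raise ValueError(f"gene {gene!r}: need >= 2 hybrid embryos")
        ref = parental_avg[gene]
        emds = np.array([emd_1d(p, ref) for p in patterns])
        t, p = _one_sided_one_sample(emds, parental_emd[gene])
        rows.append(
            {
                "gene": gene,
                "statistic": t,
                "p_value": p,
                "mean_hybrid_emd": float(emds.mean()),
                "parental_emd": float(parental_emd[gene]),
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def cross_direction_test(
    patterns: Mapping[str, Mapping[str, ExpressionPattern]],
    mother_of: Mapping[str, str],
) -> pd.DataFrame:
    """Per gene: do hybrids with different mothers differ more than replicates?

    Pairwise EMDs within each cross direction are compared to pairwise
    EMDs between directions with a two-sample one-sided t-test (between >
    within); BH correction across genes.

    ``patterns`` maps gene -> {embryo_id -> pattern}; ``mother_of`` maps
    embryo_id -> 'mel' | 'sim'.
    """
    rows = []
    for gene, per_embryo in patterns.items():
        ids = sorted(per_embryo)
        by_dir: dict[str, list[str]] = {"mel": [], "sim": []}
        for e in ids:
            by_dir[mother_of[e]].append(e)
        within = [
            emd_1d(per_embryo[a], per_embryo[b])
            for embs in by_dir.values()
            for a, b in combinations(embs, 2)
        ]
        between = [
            emd_1d(per_embryo[a], per_embryo[b])
            for a, b in product(by_dir["mel"], by_dir["sim"])
        ]
        if not between:
            raise ValueError(f"gene {gene!r}: no between-direction embryo pairs")
        if len(within) < 2 or len(between) < 2:
            raise ValueError(
                f"gene {gene!r}: need >= 2 within and >= 2 between pairs for the t-test"
            )
        res = stats.ttest_ind(between, within, alternative="greater")
        rows.append(
            {
                "gene": gene,
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue) if np.isfinite(res.pvalue) else 1.0,
                "n_within": len(within),
                "n_between": len(between),
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
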