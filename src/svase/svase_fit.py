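"""Step/peak pattern fitting along the anterior-posterior axis.

Spatially varying allele-specific expression (svASE) shows up in sliced
embryos as either a step — bias at one end of the embryo transitioning to a
different level at the other — or a confined peak/dip on a roughly constant
baseline.  Each gene's pooled ASE profile is fit by nonlinear least squares
with both curve families:

* step:  ``f(x) = A / (1 + exp(w * (x - x0))) - y0``  (logistic)
* peak:  ``f(x) = A * exp(-(x - x0)^2 / w^2) - y0``   (Gaussian)

A gene is called svASE when the better of the two fits explains at least a
fraction ``threshold`` (default 0.45) of the variance, R^2 = 1 - SSE/SST.
The false-discovery rate of the calling procedure is estimated by shuffling
the spatial coordinates of the whole ASE matrix and recounting calls.

Logistic fits are initialization-sensitive, so fitting multi-starts from a
grid of centers and widths; the grid starts are ranked by their initial SSE
and only the most promising ones are polished with a bounded trust-region
solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .containers import ASEMatrix

__all__ = [
    "FitParams",
    "FitSkipped",
    "FdrEstimate",
    "evaluate_curve",
    "fit_gene",
    "call_svase",
    "shuffle_fdr",
]

# Multi-start grids (x in fractions of egg length).
X0_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.1, 0.91, 0.1), 2))
STEP_W_GRID: tuple[float, ...] = (5.0, 20.0, 80.0, -5.0, -20.0, -80.0)
PEAK_W_GRID: tuple[float, ...] = (0.05, 0.15, 0.4)

# Parameter bounds: amplitude clamped to [-2, 2], center allowed slightly
# outside the embryo so half-visible patterns remain fittable.
_BOUNDS = {
    "step": (np.array([-2.0, -300.0, -0.25, -3.0]), np.array([2.0, 300.0, 1.25, 3.0])),
    "peak": (np.array([-2.0, 1e-3, -0.25, -3.0]), np.array([2.0, 5.0, 1.25, 3.0])),
}

KINDS = ("step", "peak")


@dataclass(frozen=True)
class FitParams:
    """Parameters of one step or peak curve."""

    kind: str
    A: float
    w: float
    x0: float
    y0: float

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "peak" and self.w == 0:
            raise ValueError("peak width w must be nonzero")
        if not np.isfinite(self.x0):
            raise ValueError("x0 must be finite")


class FitSkipped(ValueError):
    """Raised when a gene has too little spatial coverage to fit."""


def _step_curve(x: np.ndarray, A: float, w: float, x0: float, y0: float) -> np.ndarray:
    z = np.clip(w * (x - x0), -500.0, 500.0)
    return A / (1.0 + np.exp(z)) - y0


def _peak_curve(x: np.ndarray, A: float, w: float, x0: float, y0: float) -> np.ndarray:
    return A * np.exp(-((x - x0) ** 2) / w**2) - y0


def _step_jac(x: np.ndarray, A: float, w: float, x0: float, y0: float) -> np.ndarray:
    z = np.clip(w * (x - x0), -500.0, 500.0)
    u = 1.0 / (1.0 + np.exp(z))
    s = u * (1.0 - u)
    return np.column_stack([u, -A * s * (x - x0), A * s * w, -np.ones_like(x)])


def _peak_jac(x: np.ndarray, A: float, w: float, x0: float, y0: float) -> np.ndarray:
    d = x - x0
    g = np.exp(-(d**2) / w**2)
    return np.column_stack(
        [g, 2.0 * A * g * d**2 / w**3, 2.0 * A * g * d / w**2, -np.ones_like(x)]
    )


def evaluate_curve(params: FitParams, x) -> np.ndarray | float:
    """Evaluate a step or peak curve at position(s) ``x``."""
    xa = np.asarray(x, dtype=float)
    if params.kind == "step":
        out = _step_curve(xa, params.A, params.w, params.x0, params.y0)
    else:
        out = _peak_curve(xa, params.A, params.w, params.x0, params.y0)
    return out if xa.ndim else float(out)


def _canonicalize_step(p: np.ndarray) -> np.ndarray:
    """Resolve the step sign degeneracy (A,w,y0) ~ (-A,-w,y0-A) to A >= 0."""
    A, w, x0, y0 = p
    if A < 0:
        return np.array([-A, -w, x0, y0 - A])
    return p


def _start_params(x: np.ndarray, y: np.ndarray, kind: str) -> np.ndarray:
    """Data-informed starting points over the (x0, w) grid."""
    starts = []
    if kind == "step":
        for x0 in X0_GRID:
            left = y[x < x0]
            right = y[x >= x0]
            lv = left.mean() if left.size else y.mean()
            rv = right.mean() if right.size else y.mean()
            A0 = float(np.clip(lv - rv, -2.0, 2.0))
            for w in STEP_W_GRID:
                starts.append((A0 if w > 0 else -A0, w, x0, -rv if w > 0 else -lv))
    else:
        base = float(np.median(y))
        for x0 in X0_GRID:
            near = y[np.abs(x - x0) < 0.1]
            apex = near.mean() if near.size else y.mean()
            A0 = float(np.clip(apex - base, -2.0, 2.0))
            if A0 == 0.0:
                A0 = 0.1
            for w in PEAK_W_GRID:
                starts.append((A0, w, x0, -base))
    return np.array(starts, dtype=float)


def _batch_curve(params: np.ndarray, x: np.ndarray, kind: str) -> np.ndarray:
    """Curve predictions for many parameter rows at once: (B, N)."""
    A = params[:, 0:1]
    w = params[:, 1:2]
    x0 = params[:, 2:3]
    y0 = params[:, 3:4]
    if kind == "step":
        z = np.clip(w * (x[None, :] - x0), -500.0, 500.0)
        return A / (1.0 + np.exp(z)) - y0
    return A * np.exp(-((x[None, :] - x0) ** 2) / w**2) - y0


def _batch_jac(params: np.ndarray, x: np.ndarray, kind: str) -> np.ndarray:
    """Jacobians for many parameter rows at once: (B, N, 4)."""
    A = params[:, 0:1]
    w = params[:, 1:2]
    x0 = params[:, 2:3]
    d = x[None, :] - x0
    ones = np.ones((params.shape[0], x.size))
    if kind == "step":
        z = np.clip(w * d, -500.0, 500.0)
        u = 1.0 / (1.0 + np.exp(z))
        s = u * (1.0 - u)
        return np.stack([u, -A * s * d, A * s * w, -ones], axis=2)
    g = np.exp(-(d**2) / w**2)
    return np.stack(
        [g, 2.0 * A * g * d**2 / w**3, 2.0 * A * g * d / w**2, -ones], axis=2
    )


def _sse_at(params: np.ndarray, x: np.ndarray, y: np.ndarray, kind: str) -> np.ndarray:
    """Vectorized SSE of many parameter rows against one profile."""
    pred = _batch_curve(params, x, kind)
    return np.sum((pred - y[None, :]) ** 2, axis=1)


def _batched_lm(
    x: np.ndarray,
    y: np.ndarray,
    starts: np.ndarray,
    kind: str,
    lo: np.ndarray,
    hi: np.ndarray,
    n_iter: int = 60,
) -> np.ndarray:
    """Projected Levenberg-Marquardt run on all starts simultaneously.

    Returns the lowest-SSE parameter vector among the starts; a follow-up
    single-start polish provides final precision.
    """
    p = starts.copy()  # (B, 4)
    B = p.shape[0]
    lam = np.full(B, 1e-3)
    sse = _sse_at(p, x, y, kind)
    eye = np.eye(4)

    for _ in range(n_iter):
        J = _batch_jac(p, x, kind)  # (B, N, 4)
        r = _batch_curve(p, x, kind) - y[None, :]  # (B, N)
        H = J.transpose(0, 2, 1) @ J
        g = np.einsum("bnk,bn->bk", J, r)
        damp = lam[:, None, None] * (np.abs(np.diagonal(H, axis1=1, axis2=2))[:, :, None] * eye + 1e-12 * eye)
        try:
            step = np.linalg.solve(H + damp, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(
                (H + damp).reshape(-1, 4), g.reshape(-1, 1), rcond=None
            )[0].reshape(B, 4)
        p_new = np.clip(p - step, lo, hi)
        sse_new = _sse_at(p_new, x, y, kind)
        better = sse_new < sse
        p[better] = p_new[better]
        sse[better] = sse_new[better]
        lam = np.where(better, lam / 3.0, lam * 2.5)
        lam = np.clip(lam, 1e-10, 1e8)
        if better.any():
            if np.max(np.abs(step[better])) < 1e-10:
                break
        elif np.min(lam) > 1e6:
            break
    return p[np.argmin(sse)]


def fit_gene(
    x,
    y,
    kind: str,
    *,
    n_starts: int = 6,
    min_points: int = 8,
    min_span: float = 0.5,
) -> tuple[FitParams, float]:
    """Least-squares fit of one curve family to a pooled ASE profile.

    Parameters
    ----------
    x, y
        Slice positions (fraction of egg length) and ASE values, pooled
        across embryos; NaNs in ``y`` are dropped.
    kind
        ``"step"`` or ``"peak"``.
    n_starts
        Number of grid starts (ranked by initial SSE) polished by the
        bounded solver.

    Returns
    -------
    (FitParams, r2) of the lowest-SSE solution; step amplitudes are
    canonicalized to ``A >= 0``.

    Raises
    ------
    FitSkipped
        If fewer than ``min_points`` finite values remain or they span
        less than ``min_span`` of the x range.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    x, y = x[keep], y[keep]
    if x.size < min_points:
        raise FitSkipped(f"only {x.size} finite values (need >= {min_points})")
    if np.ptp(x) < min_span:
        raise FitSkipped(f"x span {np.ptp(x):.2f} < {min_span}")

    lo, hi = _BOUNDS[kind]
    starts = _start_params(x, y, kind)
    starts = np.clip(starts, lo + 1e-9, hi - 1e-9)
    order = np.argsort(_sse_at(starts, x, y, kind))[:n_starts]

    # batched damped Gauss-Newton over the retained starts, then a single
    # scipy polish of the winner for full precision
    cand = _batched_lm(x, y, starts[order], kind, lo, hi)

    curve = _step_curve if kind == "step" else _peak_curve
    jac = _step_jac if kind == "step" else _peak_jac
    sol = least_squares(
        lambda p: curve(x, *p) - y,
        np.clip(cand, lo, hi),
        jac=lambda p: jac(x, *p),
        bounds=(lo, hi),
        method="trf",
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=100,
    )
    best_p = sol.x
    best_sse = float(2.0 * sol.cost)
    if kind == "step":
        best_p = _canonicalize_step(best_p)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if sst < 1e-12 else 1.0 - best_sse / sst
    params = FitParams(kind=kind, A=best_p[0], w=best_p[1], x0=best_p[2], y0=best_p[3])
    return params, r2


def _fit_profile_both(x: np.ndarray, y: np.ndarray, **kw) -> dict[str, tuple[FitParams, float]]:
    return {kind: fit_gene(x, y, kind, **kw) for kind in KINDS}


def call_svase(
    matrix: ASEMatrix,
    threshold: float = 0.45,
    *,
    n_starts: int = 6,
    min_points: int = 8,
    min_span: float = 0.5,
) -> pd.DataFrame:
    """Fit both curve families per gene and call svASE at ``threshold``.

    Each gene is classified by the curve with the greater variance
    explained (ties toward step); ``passes`` marks genes whose best R^2
    reaches the threshold.  Genes with too little coverage appear with
    ``kind='skipped'`` and the skip reason.

    Returns a DataFrame indexed by gene with columns
    ``kind, A, w, x0, y0, r2, passes, reason``.
    """
    rows = []
    for gene in matrix.genes:
        x, y = matrix.gene_profile(gene)
        try:
            fits = _fit_profile_both(
                x, y, n_starts=n_starts, min_points=min_points, min_span=min_span
            )
        except FitSkipped as exc:
            rows.append(
                {
                    "gene": gene,
                    "kind": "skipped",
                    "A": np.nan,
                    "w": np.nan,
                    "x0": np.nan,
                    "y0": np.nan,
                    "r2": np.nan,
                    "passes": False,
                    "reason": str(exc),
                }
            )
            continue
        # tie on r2 broken toward step (dict order is step first)
        best_kind = max(KINDS, key=lambda k: (fits[k][1], k == "step"))
        params, r2 = fits[best_kind]
        rows.append(
            {
                "gene": gene,
                "kind": best_kind,
                "A": params.A,
                "w": params.w,
                "x0": params.x0,
                "y0": params.y0,
                "r2": r2,
                "passes": bool(r2 >= threshold),
                "reason": "",
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out.attrs["threshold"] = threshold
    return out


@dataclass
class FdrEstimate:
    """Shuffle-based FDR estimate for one curve family."""

    kind: str
    n_shuffles: int
    observed_calls: int
    shuffle_calls: list[int] = field(default_factory=list)

    @property
    def fdr(self) -> float:
        mean_false = float(np.mean(self.shuffle_calls)) if self.shuffle_calls else 0.0
        return mean_false / max(self.observed_calls, 1)


def _count_calls(values: np.ndarray, x: np.ndarray, threshold: float, **kw) -> dict[str, int]:
    counts = {k: 0 for k in KINDS}
    for y in values:
        keep = np.isfinite(y)
        try:
            fits = _fit_profile_both(x[keep], y[keep], **kw)
        except FitSkipped:
            continue
        best_kind = max(KINDS, key=lambda k: (fits[k][1], k == "step"))
        if fits[best_kind][1] >= threshold:
            counts[best_kind] += 1
    return counts


def shuffle_fdr(
    matrix: ASEMatrix,
    threshold: float = 0.45,
    n_shuffles: int = 1000,
    seed: int | None = 0,
    *,
    per_gene: bool = False,
    n_starts: int = 6,
    min_points: int = 8,
    min_span: float = 0.5,
) -> dict[str, FdrEstimate]:
    """Estimate the svASE calling FDR by shuffling spatial coordinates.

    Each shuffle permutes the columns of the ASE matrix (one joint
    permutation of slice positions across all genes; set ``per_gene=True``
    for independent per-gene permutations), refits both curve families and
    counts genes clearing ``threshold``.  The FDR per family is the mean
    number of shuffle calls divided by the observed calls (at least 1).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    kw = dict(n_starts=n_starts, min_points=min_points, min_span=min_span)

    values = matrix.values.to_numpy(dtype=float)
    x = matrix.x.to_numpy(dtype=float)
    observed = _count_calls(values, x, threshold, **kw)

    shuffle_counts = {k: [] for k in KINDS}
    n_cols = x.size
    for _ in range(n_shuffles):
        if per_gene:
            shuffled = np.empty_like(values)
            for i in range(values.shape[0]):
                shuffled[i] = values[i, rng.permutation(n_cols)]
            counts = _count_calls(shuffled, x, threshold, **kw)
        else:
            perm = rng.permutation(n_cols)
            counts = _count_calls(values[:, perm], x, threshold, **kw)
        for k in KINDS:
            shuffle_counts[k].append(counts[k])

    return {
        k: FdrEstimate(
            kind=k,
            n_shuffles=n_shuffles,
            observed_calls=observed[k],
            shuffle_calls=shuffle_counts[k],
        )
        for k in KINDS
    }
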