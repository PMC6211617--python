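"""Logistic model of anterior *hunchback* CRM output and perturbation scans.

The anterior *hb* expression domain is modeled as a logistic function of
nuclear transcription-factor concentrations: a linear term per TF plus a
quadratic term for Bicoid, which can lose its activating ability at the
high concentrations found at the anterior tip.  The model is trained on
nuclei carrying either the anterior stripe or no expression (the posterior
stripe, which is driven by separate regulation, is removed first).

A cis-regulatory change that strengthens or weakens one TF's input is
emulated by multiplying that TF's coefficient; predicted allele-specific
expression is the ASE score of the perturbed vs base model outputs,

    ASE(nucleus) = (p_perturbed - p_base) / (p_perturbed + p_base)

aggregated into virtual slices like the atlas bias prediction.  Scanning
TFs x multipliers and scoring each against observed per-bin ASE (after
matching means, since mapping bias can shift the observed mean) nominates
the binding change that best explains the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize

from .containers import NucleusAtlas
from .atlas_bias import normalize_atlas_gene

__all__ = [
    "CRMModel",
    "PerturbationResult",
    "build_design",
    "select_training_nuclei",
    "fit_crm_model",
    "select_model",
    "predict_expression",
    "perturb_coefficients",
    "perturb_and_predict_ase",
    "scan_perturbations",
]

QUADRATIC_TF = "bcd"


def _quad_col(tf: str) -> str:
    return f"{tf}2"


@dataclass
class CRMModel:
    """Fitted logistic CRM model: intercept + per-TF terms (+ Bcd squared)."""

    tf_list: list[str]
    coefficients: pd.Series
    pseudo_r2: float
    separation: bool = False
    quadratic_tf: str = QUADRATIC_TF

    def __post_init__(self) -> None:
        expected = self.design_columns()
        if list(self.coefficients.index) != expected:
            raise ValueError(
                f"coefficient index {list(self.coefficients.index)} does not match "
                f"design columns {expected}"
            )

    def design_columns(self) -> list[str]:
        cols = ["intercept", *self.tf_list]
        if self.quadratic_tf in self.tf_list:
            cols.append(_quad_col(self.quadratic_tf))
        return cols


def build_design(
    data: pd.DataFrame, tfs: list[str], quadratic_tf: str = QUADRATIC_TF
) -> pd.DataFrame:
    """Design matrix: intercept, one column per TF, squared Bicoid term."""
    design = pd.DataFrame(index=data.index)
    design["intercept"] = 1.0
    for tf in tfs:
        design[tf] = data[tf].astype(float)
    if quadratic_tf in tfs:
        design[_quad_col(quadratic_tf)] = design[quadratic_tf] ** 2
    return design


def select_training_nuclei(
    atlas: NucleusAtlas,
    target_gene: str,
    on_threshold: float = 0.2,
    n_bins: int = 50,
    normalized: pd.Series | None = None,
) -> tuple[pd.Index, pd.Series]:
    """Drop the posterior expression domain and binarize the response.

    The target gene's (normalized) expression is thresholded at
    ``on_threshold`` x peak; contiguous runs of "on" bins along x are the
    expression domains.  When at least two domains exist, nuclei of the
    domain with the larger x centroid (the posterior stripe) are excluded.
    Remaining nuclei are labeled on/off by the same threshold.

    Returns the retained nucleus index and the binary response.
    """
    expr = normalized if normalized is not None else normalize_atlas_gene(atlas, target_gene)
    xf = atlas.x_fraction()
    peak = float(expr.max())
    if peak <= 0:
        raise ValueError(f"target gene {target_gene!r} has no positive expression")
    thr = on_threshold * peak
    on = expr >= thr

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(xf, edges) - 1, 0, n_bins - 1)
    bin_on = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            bin_on[b] = on[sel].mean() > 0.5

    # 1-D connected components over "on" bins
    domains: list[tuple[int, int]] = []
    start = None
    for b in range(n_bins):
        if bin_on[b] and start is None:
            start = b
        elif not bin_on[b] and start is not None:
            domains.append((start, b - 1))
            start = None
    if start is not None:
        domains.append((start, n_bins - 1))

    if len(domains) < 2:
        warnings.warn(
            f"fewer than two {target_gene!r} expression domains detected; all nuclei retained"
        )
        keep = atlas.data.index
    else:
        centroids = [(lo + hi) / 2.0 for lo, hi in domains]
        lo, hi = domains[int(np.argmax(centroids))]
        in_posterior = pd.Series(
            (which >= lo) & (which <= hi), index=atlas.data.index
        ) & on
        keep = atlas.data.index[~in_posterior]
    response = on.loc[keep].astype(int)
    return keep, response


def _loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = np.clip(X @ beta, -500, 500)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def _ridge_logit(X: np.ndarray, y: np.ndarray, penalty: float) -> np.ndarray:
    """L2-penalized logistic fit (intercept unpenalized)."""
    pen_mask = np.ones(X.shape[1])
    pen_mask[0] = 0.0

    def objective(beta: np.ndarray) -> float:
        return -_loglik(beta, X, y) + penalty * float(np.sum(pen_mask * beta**2))

    def grad(beta: np.ndarray) -> np.ndarray:
        eta = np.clip(X @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        return -(X.T @ (y - mu)) + 2.0 * penalty * pen_mask * beta

    res = minimize(objective, np.zeros(X.shape[1]), jac=grad, method="L-BFGS-B")
    return res.x


def fit_crm_model(
    design: pd.DataFrame,
    response: pd.Series,
    quadratic_tf: str = QUADRATIC_TF,
    ridge_penalty: float = 1e-4,
) -> CRMModel:
    """Maximum-likelihood logistic regression of on/off expression on TFs.

    Reports McFadden's pseudo-R^2 (1 - ll_model / ll_null).  On complete
    or quasi-complete separation the fit falls back to a small ridge
    penalty and the model is flagged.
    """
    y = np.asarray(response, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("response must contain both classes")
    X = design.to_numpy(dtype=float)

    separation = False
    params: np.ndarray
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = fit.params
        if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e3 or not fit.mle_retvals.get("converged", True):
            raise RuntimeError("unstable fit")
        llf, llnull = float(fit.llf), float(fit.llnull)
    except Exception:
        separation = True
        params = _ridge_logit(X, y, ridge_penalty)
        llf = _loglik(params, X, y)
        p0 = y.mean()
        llnull = float(np.sum(y * np.log(p0) + (1 - y) * np.log1p(-p0)))

    pseudo_r2 = 1.0 - llf / llnull if llnull != 0 else 0.0
    # reconstruct the tf list from the design (everything but intercept and
    # the squared column)
    tfs = [c for c in design.columns if c not in ("intercept", _quad_col(quadratic_tf))]
    model = CRMModel(
        tf_list=tfs,
        coefficients=pd.Series(params, index=list(design.columns)),
        pseudo_r2=float(pseudo_r2),
        separation=separation,
        quadratic_tf=quadratic_tf,
    )
    return model


def predict_expression(model: CRMModel, design: pd.DataFrame) -> pd.Series:
    """Expression probability per nucleus: logistic inverse link."""
    if list(design.columns) != model.design_columns():
        raise ValueError(
            f"design columns {list(design.columns)} do not match model "
            f"{model.design_columns()}"
        )
    eta = np.clip(design.to_numpy(dtype=float) @ model.coefficients.to_numpy(), -500, 500)
    return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=design.index)


def select_model(
    atlas: NucleusAtlas,
    target_gene: str,
    required_tfs: list[str],
    candidate_tfs: list[str],
    max_extra: int = 4,
    on_threshold: float = 0.2,
    budget: int = 20000,
    quadratic_tf: str = QUADRATIC_TF,
) -> tuple[CRMModel, float]:
    """Best TF subset by fraction of expression variance explained.

    Enumerates candidate subsets of size <= ``max_extra`` (always keeping
    ``required_tfs``), fits each logistic model on the training nuclei,
    and scores it by the variance of the continuous normalized expression
    explained by the fitted probability (1 - SSE/SST).  Larger subsets must
    strictly improve the score, so ties prefer the smaller model.
    """
    if not candidate_tfs:
        raise ValueError("candidate TF list must be non-empty")
    total = sum(comb(len(candidate_tfs), r) for r in range(max_extra + 1))
    if total > budget:
        raise ValueError(
            f"{total} candidate subsets exceed the budget of {budget}; "
            "shorten the candidate list or lower max_extra"
        )

    expr = normalize_atlas_gene(atlas, target_gene)
    keep, response = select_training_nuclei(
        atlas, target_gene, on_threshold=on_threshold, normalized=expr
    )
    data = atlas.data.loc[keep]
    cont = expr.loc[keep].to_numpy(dtype=float)
    sst = float(np.sum((cont - cont.mean()) ** 2))

    best: tuple[CRMModel, float] | None = None
    for r in range(max_extra + 1):
        for extra in combinations(candidate_tfs, r):
            tfs = list(dict.fromkeys([*required_tfs, *extra]))
            design = build_design(data, tfs, quadratic_tf)
            model = fit_crm_model(design, response, quadratic_tf)
            pred = predict_expression(model, design).to_numpy()
            sse = float(np.sum((cont - pred) ** 2))
            score = 1.0 - sse / sst if sst > 0 else 0.0
            if best is None or score > best[1] + 1e-12:
                best = (model, score)
    assert best is not None
    return best


def perturb_coefficients(model: CRMModel, tf, multiplier: float) -> CRMModel:
    """Model with the named coefficient(s) multiplied.

    ``tf`` may be a single term name, a sequence of term names, or
    ``"bcd_tandem"`` to scale the linear and squared Bicoid terms together.
    """
    if isinstance(tf, str):
        if tf == f"{model.quadratic_tf}_tandem":
            terms = [model.quadratic_tf, _quad_col(model.quadratic_tf)]
        else:
            terms = [tf]
    else:
        terms = list(tf)
    coefs = model.coefficients.copy()
    for t in terms:
        if t not in coefs.index:
            raise KeyError(f"term {t!r} not in model ({list(coefs.index)})")
        coefs[t] = coefs[t] * multiplier
    return CRMModel(
        tf_list=list(model.tf_list),
        coefficients=coefs,
        pseudo_r2=model.pseudo_r2,
        separation=model.separation,
        quadratic_tf=model.quadratic_tf,
    )


@dataclass
class PerturbationResult:
    """Predicted ASE from one (tf, multiplier) coefficient perturbation."""

    tf: str
    multiplier: float
    nucleus_ase: pd.Series
    slice_ase: pd.Series  # per-bin, centered to the observed mean
    pearson_r: float = np.nan
    var_explained: float = np.nan


def perturb_and_predict_ase(
    model: CRMModel,
    tf,
    multiplier: float,
    design: pd.DataFrame,
    x_frac: pd.Series,
    bin_width: float = 0.04,
    observed_mean: float = 0.0,
    min_frac: float = 0.2,
) -> PerturbationResult:
    """Predicted per-nucleus and per-bin ASE for one coefficient change.

    The perturbed model plays the role of the *D. simulans* allele and the
    base model the *D. melanogaster* allele; per-bin ASE applies the ASE
    score to the summed predicted expression of each bin's nuclei, then is
    shifted so its mean matches ``observed_mean``.  Bins whose per-nucleus
    mean expression stays below ``min_frac`` of the peak under both models
    carry no callable ASE, mirroring the atlas bias mask.
    """
    p_base = predict_expression(model, design).to_numpy()
    p_pert = predict_expression(perturb_coefficients(model, tf, multiplier), design).to_numpy()
    total = p_base + p_pert
    with np.errstate(invalid="ignore", divide="ignore"):
        nucleus = np.where(total > 0, (p_pert - p_base) / np.where(total > 0, total, 1.0), np.nan)

    xf = np.asarray(x_frac, dtype=float)
    n_bins = int(np.ceil(1.0 / bin_width))
    which = np.minimum((xf / bin_width).astype(int), n_bins - 1)
    peak = float(np.max(np.maximum(p_base, p_pert), initial=0.0))
    centers, ase = [], []
    for b in range(n_bins):
        sel = which == b
        centers.append((b + 0.5) * bin_width)
        n = int(sel.sum())
        sb, sp = p_base[sel].sum(), p_pert[sel].sum()
        callable_ = n > 0 and (sp + sb) > 0 and max(sb, sp) / n >= min_frac * peak
        ase.append((sp - sb) / (sp + sb) if callable_ else np.nan)
    slice_ase = pd.Series(ase, index=pd.Index(centers, name="x_center"))
    finite = slice_ase.dropna()
    if len(finite):
        slice_ase = slice_ase + (observed_mean - finite.mean())

    tf_name = tf if isinstance(tf, str) else "+".join(tf)
    return PerturbationResult(
        tf=tf_name,
        multiplier=float(multiplier),
        nucleus_ase=pd.Series(nucleus, index=design.index),
        slice_ase=slice_ase,
    )


def scan_perturbations(
    model: CRMModel,
    tfs: list,
    multipliers,
    design: pd.DataFrame,
    x_frac: pd.Series,
    observed_ase: pd.Series,
    bin_width: float = 0.04,
) -> pd.DataFrame:
    """Score every (tf, multiplier) perturbation against observed ASE.

    Predicted per-bin ASE (mean-matched to the observed mean over jointly
    callable bins) is scored by Pearson correlation and by variance
    explained, 1 - SSE/SST; results are ranked by variance explained with
    ties (including the no-signal case where all scores are <= 0) broken
    toward the smallest coefficient change |multiplier - 1|.

    ``observed_ase`` must be indexed by the same bin centers the scan
    produces (use ``atlas_bias.bin_observed_ase`` or the predicted-ASE bin
    grid).
    """
    multipliers = np.asarray(list(multipliers), dtype=float)
    if multipliers.size == 0:
        raise ValueError("multiplier grid must be non-empty")
    obs = observed_ase.to_numpy(dtype=float)

    rows = []
    for tf in tfs:
        for m in multipliers:
            res = perturb_and_predict_ase(model, tf, m, design, x_frac, bin_width)
            pred = res.slice_ase.to_numpy(dtype=float)
            if pred.size != obs.size:
                raise ValueError("observed ASE is not on the scan's bin grid")
            keep = np.isfinite(pred) & np.isfinite(obs)
            if keep.sum() < 3:
                raise ValueError("fewer than 3 jointly callable bins")
            o, p = obs[keep], pred[keep]
            p = p + (o.mean() - p.mean())
            sst = float(np.sum((o - o.mean()) ** 2))
            sse = float(np.sum((o - p) ** 2))
            if sst > 0:
                var_explained = 1.0 - sse / sst
                with np.errstate(invalid="ignore"):
                    r = (
                        float(np.corrcoef(o, p)[0, 1])
                        if np.std(p) > 0 and np.std(o) > 0
                        else np.nan
                    )
            else:
                var_explained = 0.0 if sse < 1e-12 else -np.inf
                r = np.nan
            rows.append(
                {
                    "tf": res.tf,
                    "multiplier": float(m),
                    "pearson_r": r,
                    "var_explained": var_explained,
                }
            )
    out = pd.DataFrame(rows)
    out["_dist"] = np.abs(out["multiplier"] - 1.0)
    out = (
        out.sort_values(["var_explained", "_dist", "tf"], ascending=[False, True, True])
        .drop(columns="_dist")
        .reset_index(drop=True)
    )
    return out
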