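"""Synthetic embryos, slice counts, ASE matrices, atlases and reads.

Every downstream stage of the pipeline can be exercised offline with data
generated here.  The generators encode the statistical structure the
analysis assumes:

* allele-resolved slice counts — per-slice totals are Poisson around the
  target depth; a gene's maternally deposited fraction of transcripts
  carries the mother's allele outright, while zygotic reads split
  binomially between the alleles, with step/peak svASE genes modulating
  the *D. simulans* rate along the anterior-posterior axis.  The default
  maternal-fraction distribution is calibrated so pooled counts show the
  ~6.8-fold excess of maternal over paternal reads seen in sliced hybrid
  embryos (with fraction f the expected ratio is (1 + f) / (1 - f)).
* ASE matrices with a truth table of null/step/peak genes for testing the
  pattern-fitting and FDR machinery.
* paired species atlases whose target-gene expression derives from a known
  logistic TF model, with an optional coefficient change in the second
  species, so bias prediction and model/perturbation recovery are testable
  against ground truth.
* abstract SNP-bearing reads for the read-assignment rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ase_core import SyntheticRead
from .containers import AlleleCountMatrix, ASEMatrix, EmbryoSpec, NucleusAtlas
from .crm_model import CRMModel, build_design, predict_expression
from .svase_fit import FitParams, evaluate_curve

__all__ = [
    "SvaseGeneSpec",
    "TFGradient",
    "DEFAULT_TF_GRADIENTS",
    "default_crm_model",
    "default_gene_panel",
    "random_truth_params",
    "simulate_tf_profiles",
    "simulate_slice_counts",
    "simulate_svase_matrix",
    "simulate_atlas_pair",
    "simulate_reads",
]

GENE_CLASSES = ("null", "step", "peak")

# Maternal:paternal pooled read ratio observed in sliced hybrid embryos.
MATERNAL_PATERNAL_RATIO = 6.8
# (1 + f) / (1 - f) = ratio  =>  mean maternal fraction
_MEAN_MATERNAL_FRACTION = (MATERNAL_PATERNAL_RATIO - 1) / (MATERNAL_PATERNAL_RATIO + 1)
_MATERNAL_BETA_CONC = 20.0


@dataclass(frozen=True)
class SvaseGeneSpec:
    """Generative spec for one gene's expression and allelic behaviour."""

    gene_id: str
    klass: str = "null"
    true_params: FitParams | None = None
    base_expression: float = 1.0
    maternal_fraction: float = 0.0
    chromosome: str = "autosome"

    def __post_init__(self) -> None:
        if self.klass not in GENE_CLASSES:
            raise ValueError(f"klass must be one of {GENE_CLASSES}")
        if self.klass != "null" and self.true_params is None:
            raise ValueError(f"{self.klass} genes need true_params")
        if not 0.0 <= self.maternal_fraction <= 1.0:
            raise ValueError("maternal_fraction must be in [0, 1]")
        if self.base_expression <= 0:
            raise ValueError("base_expression must be positive")
        if self.chromosome not in ("autosome", "X"):
            raise ValueError("chromosome must be 'autosome' or 'X'")


@dataclass(frozen=True)
class TFGradient:
    """Idealized anterior-posterior profile of one transcription factor.

    Kinds: ``anterior`` (exponential decay from the anterior pole, Bicoid
    style), ``posterior`` (mirror image), ``terminal`` (decay from both
    poles, Huckebein style), ``gaussian`` (gap-gene-like bump).  ``decay``,
    ``center`` and ``width`` are fractions of egg length.
    """

    name: str
    kind: str
    amplitude: float = 1.0
    decay: float = 0.2
    center: float = 0.5
    width: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("anterior", "posterior", "terminal", "gaussian", "ventral", "dorsal"):
            raise ValueError(f"unknown gradient kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.decay <= 0 or self.width <= 0:
            raise ValueError("decay and width must be positive")

    def profile(self, x_frac: np.ndarray, cos_ventral: np.ndarray | None = None) -> np.ndarray:
        if self.kind == "anterior":
            return self.amplitude * np.exp(-x_frac / self.decay)
        if self.kind == "posterior":
            return self.amplitude * np.exp(-(1.0 - x_frac) / self.decay)
        if self.kind == "terminal":
            return self.amplitude * (
                np.exp(-x_frac / self.decay) + np.exp(-(1.0 - x_frac) / self.decay)
            )
        if self.kind in ("ventral", "dorsal"):
            # graded around the dorsoventral circumference (Dorsal/Zen style)
            if cos_ventral is None:
                return np.full_like(x_frac, self.amplitude * 0.5**2)
            c = cos_ventral if self.kind == "ventral" else -cos_ventral
            return self.amplitude * ((1.0 + c) / 2.0) ** (0.5 / self.width)
        return self.amplitude * np.exp(-((x_frac - self.center) ** 2) / (2.0 * self.width**2))


DEFAULT_TF_GRADIENTS: tuple[TFGradient, ...] = (
    TFGradient("bcd", "anterior", amplitude=1.0, decay=0.25),
    TFGradient("hkb", "terminal", amplitude=1.0, decay=0.07),
    TFGradient("gt", "gaussian", amplitude=1.0, center=0.2, width=0.1),
    TFGradient("kr", "gaussian", amplitude=1.0, center=0.45, width=0.12),
    TFGradient("kni", "gaussian", amplitude=1.0, center=0.65, width=0.1),
    TFGradient("tll", "posterior", amplitude=1.0, decay=0.15),
    TFGradient("twi", "ventral", amplitude=1.0, width=0.25),
    TFGradient("zen", "dorsal", amplitude=1.0, width=0.25),
)

# Additional patterned (non-regulatory) genes carried by the simulated
# atlases: real expression atlases hold ~100 spatially patterned genes, and
# the cross-species nucleus matching draws its power from that breadth.
DEFAULT_ATLAS_EXTRA_GENES: tuple[TFGradient, ...] = tuple(
    TFGradient(f"marker{i}", "gaussian", amplitude=1.0, center=c, width=w)
    for i, (c, w) in enumerate(
        [(0.1, 0.06), (0.3, 0.08), (0.5, 0.06), (0.7, 0.08), (0.9, 0.06)]
    )
) + (
    TFGradient("marker5", "ventral", amplitude=1.0, width=0.12),
    TFGradient("marker6", "dorsal", amplitude=1.0, width=0.12),
    TFGradient("marker7", "anterior", amplitude=1.0, decay=0.1),
    TFGradient("marker8", "posterior", amplitude=1.0, decay=0.1),
)


def default_crm_model() -> CRMModel:
    """Ground-truth logistic model of the anterior *hb* stripe.

    Strong Bicoid activation with a repressive quadratic term sized so the
    two nearly cancel at peak Bicoid — suppressing the anterior tip
    together with terminal Huckebein repression — plus posterior Knirps
    repression.  The resulting "on" domain spans roughly 7-50% egg length.
    """
    tfs = ["bcd", "hkb", "kni"]
    coefs = pd.Series(
        {"intercept": -2.5, "bcd": 20.0, "hkb": -4.0, "kni": -3.0, "bcd2": -18.0}
    )
    return CRMModel(tf_list=tfs, coefficients=coefs, pseudo_r2=np.nan)


def _cos_ventral(pos: np.ndarray) -> np.ndarray:
    """Cosine of the angle to the ventral midline (-y); 0 at the poles."""
    r = np.sqrt(pos[:, 1] ** 2 + pos[:, 2] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(r > 0, -pos[:, 1] / np.where(r > 0, r, 1.0), 0.0)
    return c


def _ellipsoid_positions(rng: np.random.Generator, n: int, length_um: float) -> np.ndarray:
    """Nuclei on the surface of a prolate blastoderm, anterior pole at x = 0."""
    x = np.sort(rng.uniform(0.0, length_um, n))
    radius = 0.22 * length_um
    half = length_um / 2.0
    r = radius * np.sqrt(np.clip(1.0 - ((x - half) / half) ** 2, 0.0, None))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([x, r * np.cos(phi), r * np.sin(phi)])


def simulate_tf_profiles(
    spec: EmbryoSpec,
    gradients: Sequence[TFGradient] = DEFAULT_TF_GRADIENTS,
    n_nuclei: int = 2500,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-nucleus TF concentrations on a generated blastoderm nucleus grid.

    Noise is multiplicative lognormal (``exp(N(0, noise_sd))``), keeping
    concentrations non-negative and leaving log-linear gradient recovery
    unbiased.  Deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    pos = _ellipsoid_positions(rng, n_nuclei, spec.length_um)
    xf = pos[:, 0] / spec.length_um
    data = pd.DataFrame(
        pos,
        columns=["x", "y", "z"],
        index=pd.Index([f"n{i}" for i in range(n_nuclei)], name="nucleus_id"),
    )
    cosv = _cos_ventral(pos)
    for g in gradients:
        conc = g.profile(xf, cosv)
        if noise_sd > 0:
            conc = conc * np.exp(rng.normal(0.0, noise_sd, n_nuclei))
        data[g.name] = conc
    return data


def default_gene_panel(
    n_genes: int,
    seed: int = 0,
    mean_maternal_fraction: float = _MEAN_MATERNAL_FRACTION,
    beta_concentration: float = _MATERNAL_BETA_CONC,
    x_fraction: float = 0.15,
) -> list[SvaseGeneSpec]:
    """A panel of null genes with realistic expression and maternal mix.

    Base expression is log-normal; maternal fractions are Beta-distributed
    with the mean calibrated to the pooled ~6.8 maternal:paternal read
    ratio; ``x_fraction`` of genes are placed on the X chromosome.
    """
    rng = np.random.default_rng(seed)
    a = mean_maternal_fraction * beta_concentration
    b = (1.0 - mean_maternal_fraction) * beta_concentration
    panel = []
    for i in range(n_genes):
        panel.append(
            SvaseGeneSpec(
                gene_id=f"g{i:05d}",
                klass="null",
                base_expression=float(rng.lognormal(0.0, 1.0)),
                maternal_fraction=float(rng.beta(a, b)),
                chromosome="X" if rng.random() < x_fraction else "autosome",
            )
        )
    return panel


def random_truth_params(kind: str, rng: np.random.Generator) -> FitParams:
    """Random but clearly patterned true curve parameters for one gene."""
    if kind == "step":
        return FitParams(
            kind="step",
            A=float(rng.uniform(0.3, 0.8)),
            w=float(rng.choice([-1, 1]) * rng.uniform(15.0, 60.0)),
            x0=float(rng.uniform(0.2, 0.8)),
            y0=float(rng.uniform(-0.2, 0.2)),
        )
    if kind == "peak":
        return FitParams(
            kind="peak",
            A=float(rng.choice([-1, 1]) * rng.uniform(0.3, 0.8)),
            w=float(rng.uniform(0.08, 0.2)),
            x0=float(rng.uniform(0.3, 0.7)),
            y0=float(rng.uniform(-0.2, 0.2)),
        )
    raise ValueError(f"kind must be 'step' or 'peak', got {kind!r}")


def _zygotic_sim_rate(gene: SvaseGeneSpec, x: np.ndarray) -> np.ndarray:
    """P(zygotic read is from the sim allele) along the AP axis."""
    if gene.klass == "null" or gene.true_params is None:
        return np.full_like(x, 0.5)
    ase = np.clip(evaluate_curve(gene.true_params, x), -0.999, 0.999)
    return (1.0 + ase) / 2.0


def simulate_slice_counts(
    specs: EmbryoSpec | Sequence[EmbryoSpec],
    genes: Sequence[SvaseGeneSpec],
    depth: float,
    seed: int = 0,
) -> AlleleCountMatrix:
    """Allele-resolved per-slice read counts for one or more embryos.

    ``depth`` is the expected number of assignable reads per slice, shared
    across genes proportionally to their base expression.  Maternal
    transcripts carry the mother's allele; zygotic transcripts split
    binomially with the gene's (possibly spatially varying) sim-allele
    rate.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not genes:
        raise ValueError("gene list must be non-empty")
    if isinstance(specs, EmbryoSpec):
        specs = [specs]
    rng = np.random.default_rng(seed)

    weights = np.array([g.base_expression for g in genes], dtype=float)
    lam_per_gene = depth * weights / weights.sum()

    gene_ids = [g.gene_id for g in genes]
    columns = []
    blocks = []
    for emb in specs:
        x = emb.slice_positions()
        n_sl = emb.n_slices
        n_g = len(genes)
        totals = rng.poisson(np.tile(lam_per_gene[:, None], (1, n_sl)))
        f = np.array([g.maternal_fraction for g in genes], dtype=float)
        maternal = rng.binomial(totals, np.tile(f[:, None], (1, n_sl)))
        zygotic = totals - maternal
        p_sim = np.vstack([_zygotic_sim_rate(g, x) for g in genes])
        zyg_sim = rng.binomial(zygotic, p_sim)
        zyg_mel = zygotic - zyg_sim
        if emb.mother == "sim":
            n_sim = zyg_sim + maternal
            n_mel = zyg_mel
        else:
            n_sim = zyg_sim
            n_mel = zyg_mel + maternal
        for j in range(n_sl):
            columns.append((emb.embryo_id, j + 1, "mel"))
            blocks.append(n_mel[:, j])
            columns.append((emb.embryo_id, j + 1, "sim"))
            blocks.append(n_sim[:, j])

    counts = pd.DataFrame(
        np.column_stack(blocks),
        index=pd.Index(gene_ids, name="gene"),
        columns=pd.MultiIndex.from_tuples(columns, names=["embryo", "slice", "allele"]),
    )
    chrom = pd.Series([g.chromosome for g in genes], index=gene_ids)
    return AlleleCountMatrix(counts=counts, embryos=list(specs), gene_chromosome=chrom)


def simulate_svase_matrix(
    n_null: int,
    step_specs: Sequence[FitParams],
    peak_specs: Sequence[FitParams],
    n_slices: int = 26,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_embryos: int = 1,
    null_baseline_sd: float = 0.1,
) -> tuple[ASEMatrix, pd.DataFrame]:
    """An ASE matrix with known null/step/peak structure plus a truth table.

    Null genes carry a constant per-gene baseline ASE; step and peak genes
    follow their curve exactly; iid Gaussian noise with ``noise_sd`` is
    added everywhere and values are clipped to [-1, 1].
    """
    if n_slices < 8:
        raise ValueError("n_slices must be >= 8")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    embryos = [
        EmbryoSpec(
            embryo_id=f"emb{i+1}",
            mother="mel" if i % 2 == 0 else "sim",
            sex="female",
            n_slices=n_slices,
        )
        for i in range(n_embryos)
    ]
    x_one = embryos[0].slice_positions()
    x = np.tile(x_one, n_embryos)
    columns = pd.MultiIndex.from_tuples(
        [(e.embryo_id, s + 1) for e in embryos for s in range(n_slices)],
        names=["embryo", "slice"],
    )

    rows, truth_rows, gene_ids = [], [], []

    def add_gene(gid: str, klass: str, expected: np.ndarray, params: FitParams | None) -> None:
        noisy = expected + rng.normal(0.0, noise_sd, expected.size) if noise_sd > 0 else expected
        rows.append(np.clip(noisy, -1.0, 1.0))
        gene_ids.append(gid)
        truth_rows.append(
            {
                "gene": gid,
                "klass": klass,
                "A": params.A if params else np.nan,
                "w": params.w if params else np.nan,
                "x0": params.x0 if params else np.nan,
                "y0": params.y0 if params else np.nan,
            }
        )

    for i, params in enumerate(step_specs):
        add_gene(f"step{i:03d}", "step", np.asarray(evaluate_curve(params, x)), params)
    for i, params in enumerate(peak_specs):
        add_gene(f"peak{i:03d}", "peak", np.asarray(evaluate_curve(params, x)), params)
    for i in range(n_null):
        baseline = rng.normal(0.0, null_baseline_sd)
        add_gene(f"null{i:04d}", "null", np.full(x.size, baseline), None)

    values = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, x.size)),
        index=pd.Index(gene_ids, name="gene"),
        columns=columns,
    )
    matrix = ASEMatrix(values=values, x=pd.Series(x, index=columns), embryos=embryos)
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return matrix, truth


def simulate_atlas_pair(
    spec: EmbryoSpec,
    base_model: CRMModel | None = None,
    altered_tf: str = "none",
    multiplier: float = 1.0,
    seed: int = 0,
    n_nuclei: int = 2500,
    jitter_um: float = 2.0,
    tf_noise_sd: float = 0.05,
    expr_noise_sd: float = 0.05,
    gradients: Sequence[TFGradient] = DEFAULT_TF_GRADIENTS,
    extra_genes: Sequence[TFGradient] = DEFAULT_ATLAS_EXTRA_GENES,
    target_gene: str = "hb",
    posterior_stripe: bool = False,
) -> tuple[NucleusAtlas, NucleusAtlas, pd.DataFrame]:
    """Paired species atlases with a known cis-regulatory difference.

    Species 1 ("mel") expresses ``target_gene`` according to
    ``base_model``; species 2 ("sim") uses the same model with the
    ``altered_tf`` coefficient multiplied by ``multiplier`` (``"none"``
    leaves it unchanged; ``"bcd_tandem"`` scales both Bicoid terms).  The
    second atlas shares nucleus identities but has positions jittered by
    at most ``jitter_um`` and independently re-drawn TF noise.

    The regulatory input to the target gene is the true (noiseless) TF
    concentration at each nucleus; the stored TF channels and the stored
    target expression each carry independent measurement noise
    (multiplicative lognormal ``tf_noise_sd`` and additive Gaussian
    ``expr_noise_sd`` respectively), as in a real registered atlas where
    every channel is imaged separately.

    Returns ``(atlas_mel, atlas_sim, truth)`` where ``truth`` holds the
    noiseless per-nucleus expression of both models and the resulting
    bias, evaluated at the first atlas's positions.
    """
    if base_model is None:
        base_model = default_crm_model()
    term_names = set(base_model.coefficients.index)
    if altered_tf not in ("none", f"{base_model.quadratic_tf}_tandem") and (
        altered_tf not in term_names
    ):
        raise ValueError(f"altered_tf {altered_tf!r} not a model term ({sorted(term_names)})")
    if jitter_um < 0:
        raise ValueError("jitter_um must be >= 0")
    rng = np.random.default_rng(seed)

    all_gradients = (*gradients, *extra_genes)
    data_a = simulate_tf_profiles(
        spec, all_gradients, n_nuclei=n_nuclei, noise_sd=tf_noise_sd,
        seed=int(rng.integers(2**31)),
    )

    # species 2: same nuclei, jittered positions, independent TF noise
    pos_b = data_a[["x", "y", "z"]].to_numpy().copy()
    if jitter_um > 0:
        offs = rng.normal(size=pos_b.shape)
        offs /= np.linalg.norm(offs, axis=1, keepdims=True)
        pos_b = pos_b + offs * rng.uniform(0.0, jitter_um, (len(pos_b), 1))
    data_b = pd.DataFrame(pos_b, columns=["x", "y", "z"], index=data_a.index)
    xf_b = np.clip(pos_b[:, 0] / spec.length_um, 0.0, 1.0)
    cosv_b = _cos_ventral(pos_b)
    for g in all_gradients:
        conc = g.profile(xf_b, cosv_b)
        if tf_noise_sd > 0:
            conc = conc * np.exp(rng.normal(0.0, tf_noise_sd, len(conc)))
        data_b[g.name] = conc

    alt_model = base_model
    if altered_tf != "none" and multiplier != 1.0:
        from .crm_model import perturb_coefficients

        alt_model = perturb_coefficients(base_model, altered_tf, multiplier)
    elif altered_tf != "none":
        from .crm_model import perturb_coefficients

        alt_model = perturb_coefficients(base_model, altered_tf, 1.0)

    def clean_tfs(data: pd.DataFrame) -> pd.DataFrame:
        pos = data[["x", "y", "z"]].to_numpy()
        xf = np.clip(pos[:, 0] / spec.length_um, 0.0, 1.0)
        cosv = _cos_ventral(pos)
        out = pd.DataFrame({"x": data["x"], "y": data["y"], "z": data["z"]}, index=data.index)
        for g in gradients:
            out[g.name] = g.profile(xf, cosv)
        return out

    def stripe(data: pd.DataFrame, model: CRMModel) -> np.ndarray:
        design = build_design(data, model.tf_list, model.quadratic_tf)
        expr = predict_expression(model, design).to_numpy()
        if posterior_stripe:
            xf = data["x"].to_numpy() / spec.length_um
            expr = expr + 0.9 * np.exp(-((xf - 0.85) ** 2) / (2 * 0.05**2))
        return expr

    # expression responds to the true local TF concentrations; the stored
    # channels are noisy measurements of them
    clean_a = clean_tfs(data_a)
    clean_b = clean_tfs(data_b)
    expr_a = stripe(clean_a, base_model)
    expr_b = stripe(clean_b, alt_model)
    if expr_noise_sd > 0:
        expr_a = np.clip(expr_a + rng.normal(0.0, expr_noise_sd, len(expr_a)), 0.0, None)
        expr_b = np.clip(expr_b + rng.normal(0.0, expr_noise_sd, len(expr_b)), 0.0, None)
    data_a[target_gene] = expr_a
    data_b[target_gene] = expr_b

    # noiseless truth at the first atlas's positions
    p_base = stripe(clean_a, base_model)
    p_alt = stripe(clean_a, alt_model)
    total = p_base + p_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        bias = np.where(total > 0, (p_alt - p_base) / np.where(total > 0, total, 1.0), np.nan)
    truth = pd.DataFrame(
        {"p_base": p_base, "p_alt": p_alt, "bias": bias}, index=data_a.index
    )

    return (
        NucleusAtlas(species="mel", data=data_a),
        NucleusAtlas(species="sim", data=data_b),
        truth,
    )


def simulate_reads(
    gene_id: str,
    composition: Mapping[tuple[str, ...], int],
    seed: int = 0,
) -> list[SyntheticRead]:
    """Reads with the requested multiset of SNP-allele patterns, shuffled."""
    for pattern, count in composition.items():
        if count < 0:
            raise ValueError(f"negative count for pattern {pattern!r}")
    reads = []
    i = 0
    for pattern in sorted(composition, key=repr):
        for _ in range(composition[pattern]):
            reads.append(
                SyntheticRead(read_id=f"{gene_id}_r{i}", gene_id=gene_id,
                              site_alleles=tuple(pattern))
            )
            i += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    return [reads[j] for j in order]
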