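"""Read assignment, QC filtering, ASE scoring and species-bias calls.

The ASE score of a slice is

    ASE = (n_sim - n_mel) / (n_sim + n_mel)

bounded between -1 (all reads from the *D. melanogaster* allele) and +1
(all reads from the *D. simulans* allele), and independent of sequencing
depth.  Reads are assigned to an allele only when every SNP they cover
matches a single parent; reads covering no SNP, covering alleles from both
parents, or carrying a non-parental allele are discarded as ambiguous.

The species-bias caller here is an exact binomial test on pooled allelic
counts with Benjamini-Hochberg correction, applied separately to each
direction of the cross; a gene is called biased only when both directions
agree in sign below the FDR.  (It keeps the concordance decision rule of a
negative-binomial differential framework while replacing the dispersion
machinery with the exact test.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AlleleCountMatrix, ASEMatrix, SPECIES

__all__ = [
    "SyntheticRead",
    "QcThresholds",
    "assign_read",
    "ase_score",
    "score_ase_matrix",
    "apply_qc_filters",
    "call_species_bias",
    "compare_group_ase",
    "maternal_zygotic_summary",
]


@dataclass(frozen=True)
class SyntheticRead:
    """An abstract sequencing read: the parental alleles it shows at SNPs."""

    read_id: str
    gene_id: str
    site_alleles: tuple[str, ...] = ()


@dataclass(frozen=True)
class QcThresholds:
    """Sample- and SNP-level quality thresholds.

    ``min_sample_reads`` and ``min_mapping_rate`` are strict lower bounds
    (samples exactly at the boundary are retained); ``min_slice_ase_reads``
    is the per-slice callability floor for the ASE score.
    """

    min_sample_reads: int = 1_000_000
    min_mapping_rate: float = 0.52
    min_snp_reads_per_allele: int = 10
    min_slice_ase_reads: int = 20

    def __post_init__(self) -> None:
        if (
            self.min_sample_reads < 0
            or self.min_mapping_rate < 0
            or self.min_snp_reads_per_allele < 0
            or self.min_slice_ase_reads < 0
        ):
            raise ValueError("all QC thresholds must be >= 0")


def assign_read(read: SyntheticRead) -> str:
    """Assign a read to 'mel', 'sim', or 'ambiguous' from its SNP alleles."""
    alleles = set(read.site_alleles)
    if not alleles:
        return "ambiguous"
    if not alleles.issubset(SPECIES):
        return "ambiguous"
    if len(alleles) > 1:
        return "ambiguous"
    return alleles.pop()


def ase_score(n_sim, n_mel, min_reads: int = 0):
    """ASE score (n_sim - n_mel) / (n_sim + n_mel); NaN below ``min_reads``.

    Accepts scalars or arrays; negative counts raise.
    """
    n_sim = np.asarray(n_sim, dtype=float)
    n_mel = np.asarray(n_mel, dtype=float)
    if np.nanmin(n_sim, initial=0) < 0 or np.nanmin(n_mel, initial=0) < 0:
        raise ValueError("read counts must be non-negative")
    total = n_sim + n_mel
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total >= max(min_reads, 1), (n_sim - n_mel) / total, np.nan)
    return float(out) if out.ndim == 0 else out


def score_ase_matrix(matrix: AlleleCountMatrix, min_slice_reads: int = 20) -> ASEMatrix:
    """Score ASE for every gene and slice of an allele count matrix.

    Slices with fewer than ``min_slice_reads`` assignable reads for a gene
    are reported as missing.  Slice positions are midpoints normalized per
    embryo to a [0, 1] fraction of egg length.
    """
    n_sim = matrix.allele_counts("sim")
    n_mel = matrix.allele_counts("mel")
    n_mel = n_mel.reindex(columns=n_sim.columns)
    values = pd.DataFrame(
        ase_score(n_sim.to_numpy(dtype=float), n_mel.to_numpy(dtype=float), min_slice_reads),
        index=n_sim.index,
        columns=n_sim.columns,
    )
    lut = {e.embryo_id: e for e in matrix.embryos}
    x = pd.Series(
        [(sl - 0.5) / lut[emb].n_slices for emb, sl in values.columns],
        index=values.columns,
        dtype=float,
    )
    return ASEMatrix(values=values, x=x, embryos=list(matrix.embryos))


def apply_qc_filters(
    matrix: AlleleCountMatrix,
    sample_stats: pd.DataFrame,
    snp_support: pd.DataFrame | None = None,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[AlleleCountMatrix, pd.DataFrame]:
    """Apply sample, SNP and sex-chromosome filters to a count matrix.

    Parameters
    ----------
    sample_stats
        Indexed by sample id (``"<embryo>_sl<i>"``) with columns
        ``total_reads`` and ``mapping_rate``; must cover every sample.
    snp_support
        Optional table with columns ``gene``, ``mel_reads``, ``sim_reads``
        (support pooled across all samples, one row per SNP).  Genes with
        no SNP having at least ``min_snp_reads_per_allele`` reads for each
        allele are unassignable and dropped.

    Returns the filtered matrix (failing samples' columns and X-linked
    genes in male embryos masked to NaN, unassignable genes dropped) and an
    exclusion report with columns ``item, kind, reason``.
    """
    for col in ("total_reads", "mapping_rate"):
        if col not in sample_stats.columns:
            raise ValueError(f"sample_stats missing column {col!r}")
    sample_ids = matrix.sample_ids()
    missing = [s for s in sample_ids if s not in sample_stats.index]
    if missing:
        raise ValueError(f"sample_stats missing entries for samples: {missing}")

    report_rows: list[dict] = []
    counts = matrix.counts.astype(float).copy()

    for emb, sl in counts.columns.droplevel("allele").unique():
        sid = f"{emb}_sl{sl}"
        row = sample_stats.loc[sid]
        if row["total_reads"] < thresholds.min_sample_reads:
            counts.loc[:, (emb, sl)] = np.nan
            report_rows.append({"item": sid, "kind": "sample", "reason": "min_sample_reads"})
        elif row["mapping_rate"] < thresholds.min_mapping_rate:
            counts.loc[:, (emb, sl)] = np.nan
            report_rows.append({"item": sid, "kind": "sample", "reason": "min_mapping_rate"})

    keep_genes = pd.Series(True, index=counts.index)
    if snp_support is not None and len(snp_support):
        m = thresholds.min_snp_reads_per_allele
        ok = (snp_support["mel_reads"] >= m) & (snp_support["sim_reads"] >= m)
        supported = set(snp_support.loc[ok, "gene"])
        covered = set(snp_support["gene"])
        for gene in counts.index:
            if gene in covered and gene not in supported:
                keep_genes[gene] = False
                report_rows.append(
                    {"item": gene, "kind": "gene", "reason": "min_snp_reads_per_allele"}
                )
    counts = counts.loc[keep_genes]

    # X-linked genes carry only the maternal X in males; their ASE is
    # uninformative about cis-regulation, so mask those entries.
    if matrix.gene_chromosome is not None:
        x_genes = matrix.gene_chromosome.reindex(counts.index) == "X"
        for emb_spec in matrix.embryos:
            if emb_spec.sex != "male":
                continue
            cols = [c for c in counts.columns if c[0] == emb_spec.embryo_id]
            if x_genes.any() and cols:
                counts.loc[x_genes[x_genes].index, cols] = np.nan
                for gene in x_genes[x_genes].index:
                    report_rows.append(
                        {
                            "item": f"{gene}:{emb_spec.embryo_id}",
                            "kind": "gene_embryo",
                            "reason": "x_linked_male",
                        }
                    )

    report = pd.DataFrame(report_rows, columns=["item", "kind", "reason"])
    filtered = AlleleCountMatrix(
        counts=counts,
        embryos=list(matrix.embryos),
        gene_chromosome=(
            matrix.gene_chromosome.reindex(counts.index)
            if matrix.gene_chromosome is not None
            else None
        ),
    )
    return filtered, report


def _binom_two_sided_p(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized exact two-sided binomial p at p0 = 0.5 (central method).

    At p0 = 0.5 the binomial is symmetric, so doubling the smaller tail
    equals the minimum-likelihood two-sided test.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    p = 2.0 * np.minimum(lower, upper)
    return np.clip(p, 0.0, 1.0)


def call_species_bias(matrix: AlleleCountMatrix, fdr: float = 0.05) -> pd.DataFrame:
    """Call genes consistently biased toward one species' allele.

    Counts are pooled per gene within each direction of the cross (mother
    mel vs mother sim); each direction gets an exact binomial test of the
    allelic split against 0.5 and a log2(sim/mel) fold change with a 0.5
    pseudocount, BH-corrected across genes.  A gene is ``sim_biased`` or
    ``mel_biased`` only when both directions reach q < ``fdr`` with
    concordant sign, otherwise ``none``.

    Returns a DataFrame indexed by gene with per-direction ``lfc_*`` and
    ``q_*`` columns plus the final ``call``.
    """
    directions = {e.mother for e in matrix.embryos}
    for d in SPECIES:
        if d not in directions:
            raise ValueError(f"no embryos with mother species {d!r}; need both cross directions")

    per_dir: dict[str, pd.DataFrame] = {}
    for mother in SPECIES:
        embs = [e.embryo_id for e in matrix.embryos if e.mother == mother]
        cols = [c for c in matrix.counts.columns if c[0] in embs]
        sub = matrix.counts[cols]
        n_sim = sub.xs("sim", axis=1, level="allele").sum(axis=1, min_count=1).fillna(0)
        n_mel = sub.xs("mel", axis=1, level="allele").sum(axis=1, min_count=1).fillna(0)
        lfc = np.log2((n_sim + 0.5) / (n_mel + 0.5))
        p = _binom_two_sided_p(n_sim.round().astype(int), (n_sim + n_mel).round().astype(int))
        q = multipletests(p, method="fdr_bh")[1]
        per_dir[mother] = pd.DataFrame({"lfc": lfc, "p": p, "q": q}, index=matrix.genes)

    out = pd.DataFrame(index=matrix.genes)
    for mother in SPECIES:
        out[f"lfc_{mother}"] = per_dir[mother]["lfc"]
        out[f"q_{mother}"] = per_dir[mother]["q"]

    sig = (out["q_mel"] < fdr) & (out["q_sim"] < fdr)
    sim_biased = sig & (out["lfc_mel"] > 0) & (out["lfc_sim"] > 0)
    mel_biased = sig & (out["lfc_mel"] < 0) & (out["lfc_sim"] < 0)
    out["call"] = "none"
    out.loc[sim_biased, "call"] = "sim_biased"
    out.loc[mel_biased, "call"] = "mel_biased"
    return out


def compare_group_ase(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample two-sided t-test comparing ASE between genotype groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def maternal_zygotic_summary(
    matrix: AlleleCountMatrix,
    class_annotations: Mapping[str, str],
    min_ase_counts: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Maternal-allele log2 fold change per gene, summarized per class.

    Genes need at least ``min_ase_counts`` assignable reads in at least
    half the samples; counts are oriented by each embryo's mother so the
    fold change compares the maternal to the paternal allele (0.5
    pseudocount), computed per cross direction and averaged.

    Returns ``(per_gene, summary)``: per-gene class and log2FC, and a
    per-class table with the median and gene count.
    """
    classes = ("maternal", "maternal-zygotic", "zygotic")
    bad = set(class_annotations.values()) - set(classes)
    if bad:
        raise ValueError(f"unknown annotation classes: {sorted(bad)}")

    n_sim = matrix.allele_counts("sim")
    n_mel = matrix.allele_counts("mel").reindex(columns=n_sim.columns)
    total = n_sim.fillna(0) + n_mel.fillna(0)
    n_samples = total.shape[1]
    callable_genes = (total >= min_ase_counts).sum(axis=1) >= n_samples / 2

    unannotated = [g for g in matrix.genes if g not in class_annotations]
    if unannotated:
        warnings.warn(f"{len(unannotated)} genes lack maternal/zygotic annotations; dropped")

    lut = {e.embryo_id: e for e in matrix.embryos}
    rows = []
    for gene in matrix.genes:
        if gene in class_annotations and callable_genes.get(gene, False):
            lfcs = []
            for mother in SPECIES:
                cols = [c for c in n_sim.columns if lut[c[0]].mother == mother]
                if not cols:
                    continue
                mat = (n_sim if mother == "sim" else n_mel).loc[gene, cols].sum()
                pat = (n_mel if mother == "sim" else n_sim).loc[gene, cols].sum()
                lfcs.append(np.log2((mat + 0.5) / (pat + 0.5)))
            rows.append(
                {
                    "gene": gene,
                    "klass": class_annotations[gene],
                    "maternal_log2fc": float(np.mean(lfcs)),
                }
            )
    per_gene = pd.DataFrame(rows, columns=["gene", "klass", "maternal_log2fc"]).set_index("gene")

    summary_rows = []
    for klass in classes:
        vals = per_gene.loc[per_gene["klass"] == klass, "maternal_log2fc"]
        if vals.empty:
            warnings.warn(f"class {klass!r} has no callable genes; omitted from summary")
            continue
        summary_rows.append(
            {"klass": klass, "median_log2fc": float(vals.median()), "n_genes": int(vals.size)}
        )
    summary = pd.DataFrame(summary_rows, columns=["klass", "median_log2fc", "n_genes"])
    return per_gene, summary
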