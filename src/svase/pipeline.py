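"""End-to-end orchestration: simulate -> QC -> ASE -> svASE -> EMD -> atlas -> CRM.

A single :class:`RunConfig` drives a fully reproducible demonstration run
on synthetic data: one global seed is fanned out to per-stage child seeds
by a fixed derivation, every stage writes its outputs as plain text under
the configured directory, and the machine-readable run report is a pure
function of the configuration.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ase_core, atlas_bias, crm_model, emd_patterns, svase_fit, synthetic_data
from .containers import EmbryoSpec

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("svase.pipeline")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; see field names for meaning."""

    seed: int = 0
    out_dir: str = "svase_run"
    # simulation
    n_genes: int = 200
    n_step: int = 12
    n_peak: int = 12
    depth: float = 20000.0
    # QC
    min_sample_reads: int = 1_000_000
    min_mapping_rate: float = 0.52
    min_slice_ase_reads: int = 20
    # svASE calling
    svase_threshold: float = 0.45
    n_shuffles: int = 20
    # species bias
    bias_fdr: float = 0.05
    # EMD stage
    emd_pseudocount: float = 1.0
    emd_max_genes: int = 100
    # atlas / CRM stage
    atlas_n_nuclei: int = 1500
    atlas_k: int = 30
    bin_width: float = 0.04
    min_frac: float = 0.2
    crm_altered_tf: str = "hkb"
    crm_multiplier: float = 2.0
    multiplier_start: float = -1.0
    multiplier_stop: float = 3.0
    multiplier_step: float = 0.1

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.depth < 0:
            raise ValueError("n_genes must be >= 1 and depth >= 0")
        if not 0 < self.svase_threshold or self.n_shuffles < 1:
            raise ValueError("svase_threshold must be > 0 and n_shuffles >= 1")
        if not 0 < self.bias_fdr < 1:
            raise ValueError("bias_fdr must be in (0, 1)")
        if self.emd_pseudocount < 0:
            raise ValueError("emd_pseudocount must be >= 0")
        if self.multiplier_step <= 0 or self.multiplier_stop < self.multiplier_start:
            raise ValueError("invalid multiplier grid")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file {path} does not exist")
        raw = yaml.safe_load(path.read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def multiplier_grid(self) -> np.ndarray:
        n = int(round((self.multiplier_stop - self.multiplier_start) / self.multiplier_step)) + 1
        return np.round(self.multiplier_start + self.multiplier_step * np.arange(n), 10)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Fixed fan-out of the global seed into per-stage child seeds."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _demo_embryos() -> list[EmbryoSpec]:
    """Five reciprocal-cross hybrid embryos, both sexes in each direction."""
    return [
        EmbryoSpec("melXsim1", mother="mel", sex="female", n_slices=27),
        EmbryoSpec("melXsim2", mother="mel", sex="male", n_slices=26),
        EmbryoSpec("melXsim3", mother="mel", sex="female", n_slices=25),
        EmbryoSpec("simXmel1", mother="sim", sex="female", n_slices=26),
        EmbryoSpec("simXmel2", mother="sim", sex="male", n_slices=26),
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on synthetic data and return the run report.

    Outputs (TSV/CSV/JSON) are written under ``config.out_dir``; the
    report is also written there as ``report.json``.  Identical
    configurations produce identical reports.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {"config": _jsonify(asdict(config)), "stages": {}}

    def stage(name):
        logger.info("stage %s ...", name)
        return time.time()

    # ------------------------------------------------------------------ 1
    t0 = stage("simulate")
    rng = np.random.default_rng(seeds[0])
    panel = synthetic_data.default_gene_panel(config.n_genes, seed=seeds[0])
    svase_genes = []
    for i in range(config.n_step):
        svase_genes.append(
            synthetic_data.SvaseGeneSpec(
                gene_id=f"step{i:03d}",
                klass="step",
                true_params=synthetic_data.random_truth_params("step", rng),
                base_expression=float(rng.lognormal(0.5, 0.5)),
                maternal_fraction=0.0,
            )
        )
    for i in range(config.n_peak):
        svase_genes.append(
            synthetic_data.SvaseGeneSpec(
                gene_id=f"peak{i:03d}",
                klass="peak",
                true_params=synthetic_data.random_truth_params("peak", rng),
                base_expression=float(rng.lognormal(0.5, 0.5)),
                maternal_fraction=0.0,
            )
        )
    genes = panel + svase_genes
    embryos = _demo_embryos()
    counts = synthetic_data.simulate_slice_counts(embryos, genes, config.depth, seed=seeds[1])
    counts.write_tsv(out / "counts.tsv", out / "embryos.tsv")
    truth = pd.DataFrame(
        [
            {
                "gene": g.gene_id,
                "klass": g.klass,
                "maternal_fraction": g.maternal_fraction,
                "A": g.true_params.A if g.true_params else np.nan,
                "w": g.true_params.w if g.true_params else np.nan,
                "x0": g.true_params.x0 if g.true_params else np.nan,
                "y0": g.true_params.y0 if g.true_params else np.nan,
            }
            for g in genes
        ]
    ).set_index("gene")
    truth.to_csv(out / "truth.tsv", sep="\t")
    report["stages"]["simulate"] = {
        "n_genes": len(genes),
        "n_embryos": len(embryos),
        "seconds": round(time.time() - t0, 2),
    }

    # ------------------------------------------------------------------ 2
    t0 = stage("qc")
    rng_qc = np.random.default_rng(seeds[2])
    sample_ids = counts.sample_ids()
    stats = pd.DataFrame(
        {
            "total_reads": rng_qc.lognormal(np.log(3e6), 0.3, len(sample_ids)).astype(int),
            "mapping_rate": np.clip(rng_qc.normal(0.8, 0.05, len(sample_ids)), 0, 1),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    # two deliberately failing samples so the exclusion report is exercised
    stats.iloc[0, stats.columns.get_loc("total_reads")] = 900_000
    stats.iloc[1, stats.columns.get_loc("mapping_rate")] = 0.40
    filtered, qc_report = ase_core.apply_qc_filters(
        counts,
        stats,
        thresholds=ase_core.QcThresholds(
            min_sample_reads=config.min_sample_reads,
            min_mapping_rate=config.min_mapping_rate,
            min_slice_ase_reads=config.min_slice_ase_reads,
        ),
    )
    qc_report.to_csv(out / "qc_exclusions.tsv", sep="\t", index=False)
    report["stages"]["qc"] = {
        "n_excluded_samples": int((qc_report["kind"] == "sample").sum()),
        "n_masked_gene_embryos": int((qc_report["kind"] == "gene_embryo").sum()),
        "seconds": round(time.time() - t0, 2),
    }

    # ------------------------------------------------------------------ 3
    t0 = stage("ase")
    ase = ase_core.score_ase_matrix(filtered, min_slice_reads=config.min_slice_ase_reads)
    ase.write_tsv(out / "ase.tsv")
    vals = ase.values.to_numpy()
    report["stages"]["ase"] = {
        "n_callable_entries": int(np.isfinite(vals).sum()),
        "n_entries": int(vals.size),
        "seconds": round(time.time() - t0, 2),
    }

    # ------------------------------------------------------------------ 4
    t0 = stage("svase")
    calls = svase_fit.call_svase(ase, threshold=config.svase_threshold)
    calls.to_csv(out / "svase_calls.tsv", sep="\t")
    fdr = svase_fit.shuffle_fdr(
        ase, threshold=config.svase_threshold, n_shuffles=config.n_shuffles, seed=seeds[3]
    )
    true_pattern = truth.index[truth["klass"] != "null"]
    called_ok = sum(
        bool(calls.loc[g, "passes"]) and calls.loc[g, "kind"] == truth.loc[g, "klass"]
        for g in true_pattern
        if g in calls.index
    )
    null_fp = int(
        sum(bool(calls.loc[g, "passes"]) for g in truth.index[truth["klass"] == "null"]
            if g in calls.index)
    )
    report["stages"]["svase"] = {
        "n_step_calls": int(((calls["kind"] == "step") & calls["passes"]).sum()),
        "n_peak_calls": int(((calls["kind"] == "peak") & calls["passes"]).sum()),
        "class_accuracy": round(called_ok / max(len(true_pattern), 1), 4),
        "null_false_calls": null_fp,
        "fdr_step": round(fdr["step"].fdr, 6),
        "fdr_peak": round(fdr["peak"].fdr, 6),
        "seconds": round(time.time() - t0, 2),
    }

    # ------------------------------------------------------------------ 5
    t0 = stage("species_bias")
    bias = ase_core.call_species_bias(filtered, fdr=config.bias_fdr)
    bias.to_csv(out / "species_bias.tsv", sep="\t")
    report["stages"]["species_bias"] = {
        "n_mel_biased": int((bias["call"] == "mel_biased").sum()),
        "n_sim_biased": int((bias["call"] == "sim_biased").sum()),
        "seconds": round(time.time() - t0, 2),
    }

    # ------------------------------------------------------------------ 6
    t0 = stage("emd")
    emd_genes = [g.gene_id for g in genes[: config.emd_max_genes]]
    total = filtered.allele_counts("mel").fillna(0) + filtered.allele_counts("sim").fillna(0)
    # parental embryos simulated from the same gene panel (pure species)
    parents = [
        EmbryoSpec("mel_parent", mother="mel", sex="female", n_slices=26),
        EmbryoSpec("sim_parent", mother="sim", sex="female", n_slices=27),
    ]
    pcounts = synthetic_data.simulate_slice_counts(parents, genes, config.depth, seed=seeds[4])
    ptotal = pcounts.allele_counts("mel").fillna(0) + pcounts.allele_counts("sim").fillna(0)
    mother_of = {e.embryo_id: e.mother for e in embryos}
    hybrid_patterns: dict[str, list] = {}
    direction_patterns: dict[str, dict] = {}
    parental_avg: dict = {}
    parental_emd: dict = {}
    n27 = 27
    for gene in emd_genes:
        mel_prof = ptotal.loc[gene, "mel_parent"].to_numpy(dtype=float)
        sim_prof = ptotal.loc[gene, "sim_parent"].to_numpy(dtype=float)
        try:
            ref, pemd = emd_patterns.parental_reference(
                mel_prof + config.emd_pseudocount, sim_prof + config.emd_pseudocount, n_out=n27
            )
        except ValueError:
            continue
        hyb, per_emb = [], {}
        for emb in embryos:
            prof = total.loc[gene, emb.embryo_id].to_numpy(dtype=float)
            res = emd_patterns.resample_pattern(prof + config.emd_pseudocount, n27)
            if res.sum() <= 0:
                continue
            pat = emd_patterns.ExpressionPattern(
                weights=tuple(res / res.sum()), gene_id=gene, embryo_id=emb.embryo_id
            )
            hyb.append(pat)
            per_emb[emb.embryo_id] = pat
        if len(hyb) >= 2:
            hybrid_patterns[gene] = hyb
            parental_avg[gene] = ref
            parental_emd[gene] = pemd
        if len(per_emb) == len(embryos):
            direction_patterns[gene] = per_emb
    hyb_res = emd_patterns.hybrid_misexpression_test(hybrid_patterns, parental_avg, parental_emd)
    hyb_res.to_csv(out / "emd_hybrid.tsv", sep="\t")
    dir_res = emd_patterns.cross_direction_test(direction_patterns, mother_of)
    dir_res.to_csv(out / "emd_direction.tsv", sep="\t")
    report["stages"]["emd"] = {
        "n_genes_tested": int(len(hyb_res)),
        "n_hybrid_q05": int((hyb_res["q_value"] < 0.05).sum()),
        "n_direction_q05": int((dir_res["q_value"] < 0.05).sum()),
        "seconds": round(time.time() - t0, 2),
    }

    # ------------------------------------------------------------------ 7
    t0 = stage("atlas_crm")
    model = synthetic_data.default_crm_model()
    atlas_spec = EmbryoSpec("atlas", mother="mel", sex="female")
    atlas_mel, atlas_sim, atlas_truth = synthetic_data.simulate_atlas_pair(
        atlas_spec,
        model,
        config.crm_altered_tf,
        config.crm_multiplier,
        seed=seeds[5],
        n_nuclei=config.atlas_n_nuclei,
    )
    atlas_mel.write_csv(out / "atlas_mel.csv")
    atlas_sim.write_csv(out / "atlas_sim.csv")
    match_genes = atlas_mel.gene_columns
    pairing = atlas_bias.match_nuclei(atlas_mel, atlas_sim, match_genes, k=config.atlas_k)
    f_mel = atlas_mel.data["hb"].to_numpy()
    f_sim = atlas_sim.data.loc[pairing.values, "hb"].to_numpy()
    xf = atlas_mel.x_fraction()
    predicted = atlas_bias.predicted_slice_ase(
        xf.to_numpy(), f_mel, f_sim, bin_width=config.bin_width, min_frac=config.min_frac
    )
    predicted.to_csv(out / "predicted_slice_ase.tsv", sep="\t", index=False)

    # "observed" per-bin ASE: the generator's noiseless truth measured with
    # slice-level noise
    rng_obs = np.random.default_rng(seeds[6])
    n_bins = len(predicted)
    which = np.minimum((xf.to_numpy() / config.bin_width).astype(int), n_bins - 1)
    tb = atlas_truth["bias"].to_numpy()
    wsum = (atlas_truth["p_base"] + atlas_truth["p_alt"]).to_numpy()
    peak_w = float(wsum.max())
    observed = np.full(n_bins, np.nan)
    for i in range(n_bins):
        sel = which == i
        if sel.any() and wsum[sel].sum() / sel.sum() >= config.min_frac * peak_w / 2.0:
            observed[i] = float(np.average(tb[sel], weights=wsum[sel])) + rng_obs.normal(0, 0.02)
    observed_s = pd.Series(observed, index=predicted["x_center"].to_numpy())
    r = atlas_bias.correlate_predicted(predicted["ase"].to_numpy(), observed)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr = atlas_bias.normalize_atlas_gene(atlas_mel, "hb")
        keep, resp = crm_model.select_training_nuclei(atlas_mel, "hb", normalized=expr)
        design_train = crm_model.build_design(atlas_mel.data.loc[keep], model.tf_list)
        fitted = crm_model.fit_crm_model(design_train, resp)
        design_all = crm_model.build_design(atlas_mel.data, model.tf_list)
        scan = crm_model.scan_perturbations(
            fitted,
            ["bcd", "bcd2", "hkb", "kni", "bcd_tandem"],
            config.multiplier_grid(),
            design_all,
            xf,
            observed_s,
            bin_width=config.bin_width,
        )
    scan.to_csv(out / "crm_scan.tsv", sep="\t", index=False)
    fitted.coefficients.rename_axis("term").to_frame("coefficient").to_csv(
        out / "crm_model.tsv", sep="\t"
    )
    top = scan.iloc[0]
    report["stages"]["atlas_crm"] = {
        "predicted_observed_r": round(float(r), 4),
        "crm_pseudo_r2": round(float(fitted.pseudo_r2), 4),
        "top_tf": str(top["tf"]),
        "top_multiplier": float(top["multiplier"]),
        "top_var_explained": round(float(top["var_explained"]), 4),
        "seconds": round(time.time() - t0, 2),
    }

    report["total_seconds"] = round(time.time() - t_start, 2)
    # timings vary run to run; the deterministic portion excludes them
    det = json.loads(json.dumps(_jsonify(report)))
    for st in det["stages"].values():
        st.pop("seconds", None)
    det.pop("total_seconds", None)
    (out / "report.json").write_text(json.dumps(det, indent=2, sort_keys=True))
    logger.info("pipeline finished in %.1fs", time.time() - t_start)
    return det
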