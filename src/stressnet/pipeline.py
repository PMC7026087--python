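"""End-to-end orchestration: configuration, stage seeding, IO, demo.

Stage order mirrors the analysis: preprocess -> differential expression
(with gonadal/genetic attribution) -> RRHO coherence per sex and region
pair -> co-expression modules on the stressed network with preservation
against the non-stressed network -> per-sex MDC -> per-sex, per-condition
hub networks.  A single global seed is fanned out to per-stage seeds
through numpy SeedSequence spawn keys indexed by stage position, so any
stage can be rerun in isolation with the same stream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, diffexpr, hubnet, mdc, rrho
from .preprocess import (CountMatrix, ExpressionMatrix, filter_low_expression,
                         log_cpm, validate_design, voom_weights)
from .simulate import (PlantedModule, SimConfig, StressEffect,
                       generate_design, simulate_counts)

log = logging.getLogger("stressnet")

STAGES = ("simulate", "preprocess", "diffexpr", "rrho", "coexpression",
          "mdc", "hubnet")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence(global_seed) spawned at
    the stage's position in the fixed stage order."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: CountMatrix, path) -> None:
    counts.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


def read_counts_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df.index.to_numpy(dtype=object),
                       df.to_numpy(dtype=np.int64),
                       df.columns.to_numpy(dtype=object))


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> pd.DataFrame:
    return validate_design(pd.read_csv(path, sep="\t"))


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().rename_axis("gene_id").to_csv(path, sep="\t",
                                                  float_format="%.6g")


def write_counts_mtx(counts: CountMatrix, path) -> None:
    """Sparse triplet (MatrixMarket-style) writer for the count matrix."""
    g, s = counts.counts.nonzero()
    with open(path, "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{counts.n_genes} {counts.n_samples} {len(g)}\n")
        for i, j in zip(g, s):
            fh.write(f"{i + 1} {j + 1} {counts.counts[i, j]}\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    counts_path: str = "counts.tsv"
    design_path: str = "design.tsv"
    out_dir: str = "stressnet_out"
    # preprocess
    filter_fraction: float = 0.25
    prior_count: float = 0.5
    use_weights: bool = False
    # diffexpr
    moderated: bool = False
    p_max: float = 0.05
    fc_min: float = 1.3
    # rrho
    rrho_step: int | None = None
    rrho_alpha: float = 0.05
    # network
    beta: float = 6.0
    network_kind: str = "unsigned"
    estimator: str = "pearson"
    cut_height: float = 0.95
    min_module_size: int = 30
    preservation_perms: int = 200
    # mdc
    mdc_perms: int = 1000
    mdc_q_max: float = 0.05
    # hubs
    hub_method: str = "correlation"
    n_hops: int = 2
    hub_z_min: float = 2.0
    edge_score_min: float = 0.95
    hub_edge_threshold: float | None = 0.5
    max_hub_modules: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.counts_path).exists():
            raise FileNotFoundError(f"counts file not found: {self.counts_path}")
        if not Path(self.design_path).exists():
            raise FileNotFoundError(f"design file not found: {self.design_path}")
        if not 0 <= self.filter_fraction < 1:
            raise ValueError("filter_fraction must be in [0, 1)")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.mdc_perms < 100:
            raise ValueError("mdc_perms must be >= 100")
        if self.preservation_perms < 50:
            raise ValueError("preservation_perms must be >= 50")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _stress_contrast(region: str, sex: str) -> diffexpr.Contrast:
    return diffexpr.Contrast(
        name=f"stress_{region}_{sex}",
        group_a=(("stress", "stress"),),
        group_b=(("stress", "ctrl"),),
        stratum=(("region", region), ("gonadal_sex", sex)))


def default_contrasts(regions) -> list[diffexpr.Contrast]:
    """Sex-attribution contrasts (pooled over regions, non-stressed samples)
    plus per-region, per-gonadal-sex stress contrasts.

    All sex contrasts are oriented female/XX side first, so planted
    female-high genes get positive effects in all three.
    """
    out = [
        diffexpr.Contrast("sex_XXF_vs_XYM",
                          (("genotype", "XX_F"),), (("genotype", "XY_M"),),
                          (("stress", "ctrl"),)),
        diffexpr.Contrast("gonadal_F_vs_M",
                          (("gonadal_sex", "F"),), (("gonadal_sex", "M"),),
                          (("stress", "ctrl"),)),
        diffexpr.Contrast("genetic_XX_vs_XY",
                          (("genetic_sex", "XX"),), (("genetic_sex", "XY"),),
                          (("stress", "ctrl"),)),
    ]
    for region in regions:
        for sex in ("F", "M"):
            out.append(_stress_contrast(region, sex))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "outputs": {}, "stages": {}}

    def _record(stage: str, name: str, path: Path) -> None:
        manifest["outputs"][f"{stage}/{name}"] = str(path)

    # ---- preprocess -------------------------------------------------------
    counts = read_counts_tsv(config.counts_path)
    design = read_design_tsv(config.design_path)
    if list(counts.sample_ids) != list(design["sample_id"]):
        raise ValueError("counts columns and design rows disagree")
    filtered = filter_low_expression(counts, config.filter_fraction)
    expr = log_cpm(filtered, config.prior_count)
    if config.use_weights:
        expr = voom_weights(expr, filtered)
    log.info("preprocess: %d -> %d genes, %d samples",
             counts.n_genes, filtered.n_genes, filtered.n_samples)
    p = out / "expression.tsv"
    write_expression_tsv(expr, p)
    _record("preprocess", "expression", p)
    manifest["stages"]["preprocess"] = {
        "n_genes_in": counts.n_genes, "n_genes_kept": filtered.n_genes}

    # ---- differential expression -----------------------------------------
    regions = list(pd.unique(design["region"]))
    de_results: dict = {}
    de_called: dict = {}
    for contrast in default_contrasts(regions):
        res = diffexpr.de_test(expr, design, contrast,
                               moderated=config.moderated)
        de_results[contrast.name] = res
        de_called[contrast.name] = diffexpr.call_de(res, config.p_max,
                                                    config.fc_min)
        p = out / f"de_{contrast.name}.tsv"
        res.to_csv(p, sep="\t", float_format="%.6g")
        _record("diffexpr", contrast.name, p)
    venn = diffexpr.attribute_sex_differences(
        de_called["sex_XXF_vs_XYM"], de_called["gonadal_F_vs_M"],
        de_called["genetic_XX_vs_XY"])
    p = out / "sex_attribution.tsv"
    venn.to_frame().to_csv(p, sep="\t", index=False)
    _record("diffexpr", "sex_attribution", p)
    manifest["stages"]["diffexpr"] = {
        "n_called": {k: int(len(v)) for k, v in de_called.items()},
        "pct_gonadal": venn.pct_gonadal, "pct_genetic": venn.pct_genetic}

    # ---- RRHO coherence per sex and region pair --------------------------
    rrho_calls = {}
    for sex in ("F", "M"):
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                ra, rb = regions[i], regions[j]
                la = rrho.make_ranked_list(de_results[f"stress_{ra}_{sex}"])
                lb = rrho.make_ranked_list(de_results[f"stress_{rb}_{sex}"])
                rmap = rrho.rrho_map(la, lb, config.rrho_step)
                thr = rrho.bonferroni_threshold(rmap, config.rrho_alpha)
                summary = rrho.classify_quadrants(rmap, thr)
                key = f"{sex}_{ra}_vs_{rb}"
                rrho_calls[key] = summary.call
                p = out / f"rrho_{key}.tsv"
                rmap.to_frame().to_csv(p, sep="\t", float_format="%.4g")
                _record("rrho", key, p)
                p = out / f"rrho_{key}_quadrants.tsv"
                summary.to_frame().to_csv(p, sep="\t", index=False)
                _record("rrho", f"{key}_quadrants", p)
    manifest["stages"]["rrho"] = {"calls": rrho_calls}

    # ---- co-expression modules on the stressed network -------------------
    seed_coex = stage_seed(config.seed, "coexpression")
    stressed_ids = design.loc[design["stress"] == "stress", "sample_id"]
    ctrl_ids = design.loc[design["stress"] == "ctrl", "sample_id"]
    expr_stress = expr.subset_samples(stressed_ids)
    expr_ctrl = expr.subset_samples(ctrl_ids)
    adj = coexpression.adjacency(expr_stress, config.beta,
                                 config.network_kind, config.estimator)
    tom = coexpression.topological_overlap(adj)
    modules = coexpression.detect_modules(tom, expr.gene_ids,
                                          config.min_module_size,
                                          config.cut_height)
    p = out / "modules.tsv"
    modules.assignment().rename_axis("gene").to_csv(p, sep="\t")
    _record("coexpression", "modules", p)
    preservation = coexpression.module_preservation(
        modules, expr_stress, expr_ctrl, config.preservation_perms,
        seed=seed_coex, beta=config.beta, kind=config.network_kind,
        estimator=config.estimator)
    p = out / "module_preservation.tsv"
    preservation.table.to_csv(p, sep="\t", index=False, float_format="%.6g")
    _record("coexpression", "preservation", p)
    preserved = set(preservation.preserved_modules())
    module_map = {k: v for k, v in modules.modules().items() if k in preserved}
    log.info("coexpression: %d modules, %d preserved",
             len(modules.modules()), len(preserved))
    manifest["stages"]["coexpression"] = {
        "n_modules": len(modules.modules()), "n_preserved": len(preserved)}

    # ---- MDC per sex ------------------------------------------------------
    seed_mdc = stage_seed(config.seed, "mdc")
    mdc_tables = {}
    for sex in ("F", "M"):
        sel = design["gonadal_sex"] == sex
        es = expr.subset_samples(
            design.loc[sel & (design["stress"] == "stress"), "sample_id"])
        ec = expr.subset_samples(
            design.loc[sel & (design["stress"] == "ctrl"), "sample_id"])
        if not module_map:
            mdc_tables[sex] = pd.DataFrame(
                columns=["module", "mdc", "call"])
            continue
        table = mdc.mdc_analysis(es, ec, module_map, config.mdc_perms,
                                 seed=seed_mdc + (0 if sex == "F" else 1),
                                 beta=config.beta, kind=config.network_kind,
                                 q_max=config.mdc_q_max)
        mdc_tables[sex] = table
        p = out / f"mdc_{sex}.tsv"
        table.to_csv(p, sep="\t", index=False, float_format="%.6g")
        _record("mdc", sex, p)
        p = out / f"mdc_{sex}_proportions.tsv"
        mdc.call_proportions(table).to_csv(p, sep="\t", index=False)
        _record("mdc", f"{sex}_proportions", p)
    manifest["stages"]["mdc"] = {
        sex: ({} if t.empty else dict(zip(t["module"], t["call"])))
        for sex, t in mdc_tables.items()}

    # ---- hub networks -----------------------------------------------------
    seed_hub = stage_seed(config.seed, "hubnet")
    changed = [m for m in sorted(module_map)
               if any(not t.empty
                      and (t.loc[t["module"] == m, "call"] != "unchanged").any()
                      for t in mdc_tables.values())]
    focus = changed[: config.max_hub_modules]
    hub_summary: dict = {}
    for mod_name in focus:
        genes = module_map[mod_name]
        for sex in ("F", "M"):
            sel = design["gonadal_sex"] == sex
            reports = {}
            for cond in ("stress", "ctrl"):
                sub = expr.subset_samples(
                    design.loc[sel & (design["stress"] == cond),
                               "sample_id"]).subset_genes(genes)
                net = hubnet.build_condition_network(
                    sub, method=config.hub_method,
                    edge_threshold=config.hub_edge_threshold,
                    seed=seed_hub)
                reports[cond] = hubnet.identify_hubs(
                    net, config.n_hops, config.hub_z_min)
                if cond == "stress":
                    edges = hubnet.export_edges(net, config.edge_score_min)
                    p = out / f"edges_{mod_name}_{sex}_{cond}.tsv"
                    edges.to_csv(p, sep="\t", index=False,
                                 float_format="%.4g")
                    _record("hubnet", f"edges_{mod_name}_{sex}", p)
            specific = hubnet.stress_specific_hubs(reports["stress"],
                                                   reports["ctrl"])
            report = reports["stress"].copy()
            report["stress_specific"] = report.index.isin(specific)
            p = out / f"hubs_{mod_name}_{sex}.tsv"
            report.to_csv(p, sep="\t", float_format="%.4g")
            _record("hubnet", f"hubs_{mod_name}_{sex}", p)
            hub_summary[f"{mod_name}_{sex}"] = {
                "n_hubs": int(report["hub"].sum()),
                "n_stress_specific": len(specific)}
    manifest["stages"]["hubnet"] = hub_summary

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------

def demo_sim_config(seed: int = 0, n_genes: int = 2400) -> SimConfig:
    """Synthetic dataset reproducing the study's qualitative pattern.

    Plants gonadal-only, genetic-only and shared sex effects; a female
    anti-coherent BLA/NAc region pair and a male coherent PFC/NAc pair;
    five modules, one of which (planted as the analogue of the 'yellow'
    module) gains connectivity with stress in females and loses it in
    males.
    """
    width = max(5, len(str(n_genes)))
    ids = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]
    # reserve the tail of the universe for planted structure
    mod_genes = [tuple(ids[-(50 * (k + 1)): len(ids) - 50 * k])
                 for k in range(5)]
    shared = tuple(ids[-450:-250])          # stress-coherence genes
    # module detection runs on the pooled stressed network and preservation
    # against the non-stressed one, so demo modules keep stressed
    # correlation high enough to be found (>~0.6 pooled) and control
    # correlation high enough to survive preservation (>~0.4)
    modules = (
        PlantedModule("m_sex_opposite", mod_genes[0], 0.55,
                      (("F", 0.85), ("M", 0.15))),
        PlantedModule("m_gain_both", mod_genes[1], 0.45,
                      (("F", 0.8), ("M", 0.8))),
        PlantedModule("m_loss_both", mod_genes[2], 0.85,
                      (("F", 0.55), ("M", 0.55))),
        PlantedModule("m_stable_1", mod_genes[3], 0.6,
                      (("F", 0.6), ("M", 0.6))),
        PlantedModule("m_stable_2", mod_genes[4], 0.6,
                      (("F", 0.6), ("M", 0.6))),
    )
    stress_effects = (
        # anti-coherent BLA/NAc pair in females
        StressEffect(shared[:100], 1.0, region="BLA", sex="F"),
        StressEffect(shared[:100], -1.0, region="NAc", sex="F"),
        StressEffect(shared[100:], -1.0, region="BLA", sex="F"),
        StressEffect(shared[100:], 1.0, region="NAc", sex="F"),
        # coherent PFC/NAc pair in males
        StressEffect(shared[:100], 1.0, region="PFC", sex="M"),
        StressEffect(shared[:100], 1.0, region="NAc", sex="M"),
        StressEffect(shared[100:], -1.0, region="PFC", sex="M"),
        StressEffect(shared[100:], -1.0, region="NAc", sex="M"),
    )
    return SimConfig(n_genes=n_genes, n_per_cell=3,
                     de_frac_gonadal=0.03, de_frac_genetic=0.01,
                     de_frac_both=0.01, sex_effect_size=1.5,
                     stress_effects=stress_effects, modules=modules,
                     seed=seed)


def make_demo(seed: int, out_dir, n_genes: int = 2400,
              filter_fraction: float = 0.0) -> PipelineConfig:
    """Write a ready-to-run synthetic dataset + config; returns the config.

    The demo keeps ``filter_fraction`` at 0 by default so that planted
    gene sets survive verbatim; pass 0.25 to exercise the full filter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = demo_sim_config(stage_seed(seed, "simulate"), n_genes)
    design = generate_design(sim)
    counts, truth = simulate_counts(sim, design)
    write_counts_tsv(counts, out / "counts.tsv")
    write_design_tsv(design, out / "design.tsv")
    with open(out / "truth.json", "w") as fh:
        fh.write(truth.to_json())
    config = PipelineConfig(
        counts_path=str(out / "counts.tsv"),
        design_path=str(out / "design.tsv"),
        out_dir=str(out / "results"),
        filter_fraction=filter_fraction,
        min_module_size=30,
        mdc_perms=200 if n_genes <= 3000 else 1000,
        preservation_perms=100,
        seed=seed)
    config.to_yaml(out / "config.yaml")
    return config
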