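"""Synthetic factorial RNA-seq generator with planted ground truth.

Emulates a four-core-genotypes (FCG) x chronic-stress x brain-region
design: counts are negative-binomial around a log2-scale mean built from a
per-gene baseline, planted sex effects attributable to gonadal sex,
genetic (chromosomal) sex or both, planted stress effects with region- and
sex-specific sign structure, and planted co-expression modules whose
within-module correlation can change with stress in a sex-dependent
direction.

Module correlation is induced by a per-module, per-sample standard-normal
latent factor added on the log2-mean scale.  The loading for gene g under
within-module target correlation rho is

    lambda_g = sqrt(rho / (1 - rho)) * sigma_g

where sigma_g approximates the gene's counting noise on the log2 scale
(sqrt(1/mu + phi) / ln 2).  The negative-binomial noise then plays the
role of the idiosyncratic term, so the expected pairwise correlation of
log2 expression equals rho for every gene pair in the module.

Everything planted is recorded in :class:`SimTruth`; the same seed yields
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import (CountMatrix, GENOTYPE_MAP, GENOTYPES, log_cpm,
                         validate_design)

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StressEffect:
    """A planted stress effect: log2 shift applied to ``genes`` in stressed
    samples of the given region (None = all regions) and gonadal sex
    (None = both sexes)."""

    genes: tuple
    log2_effect: float
    region: str | None = None
    sex: str | None = None          # gonadal sex "F"/"M" or None


@dataclass(frozen=True)
class PlantedModule:
    """A planted co-expression module with condition-dependent correlation."""

    name: str
    gene_ids: tuple
    cor_ctrl: float
    cor_stress_by_sex: tuple = (("F", 0.0), ("M", 0.0))  # ((sex, rho), ...)

    def __post_init__(self):
        if len(self.gene_ids) < 3:
            raise ValueError(f"module {self.name}: size must be >= 3")
        cors = [self.cor_ctrl] + [c for _, c in self.cor_stress_by_sex]
        for c in cors:
            if not 0 <= c < 1:
                raise ValueError(
                    f"module {self.name}: correlations must be in [0, 1)")

    def cor_for(self, stress: str, gonadal_sex: str) -> float:
        if stress == "ctrl":
            return self.cor_ctrl
        return dict(self.cor_stress_by_sex)[gonadal_sex]


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the emulated study design
    (3 pooled replicates x 4 FCG genotypes x 3 regions x 2 stress arms)."""

    n_genes: int = 24_421
    n_per_cell: int = 3
    genotypes: tuple = GENOTYPES
    regions: tuple = ("BLA", "PFC", "NAc")
    baseline_log_mean_range: tuple = (4.0, 10.0)
    dispersion: float | tuple | None = None   # None -> logU[0.05, 0.5] per gene
    lib_size_range: tuple = (0.7, 1.4)
    de_frac_gonadal: float = 0.0
    de_frac_genetic: float = 0.0
    de_frac_both: float = 0.0
    sex_effect_size: float = 1.0
    stress_effects: tuple = ()                # StressEffect entries
    modules: tuple = ()                       # PlantedModule entries
    seed: int = 0

    def validate(self) -> None:
        if not self.genotypes or not self.regions:
            raise ValueError("genotypes and regions must be non-empty")
        for g in self.genotypes:
            if g not in GENOTYPE_MAP:
                raise ValueError(f"unknown genotype {g}")
        fracs = (self.de_frac_gonadal, self.de_frac_genetic, self.de_frac_both)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("DE fractions must lie in [0,1] and sum to <= 1")
        if self.n_genes < 1 or self.n_per_cell < 1:
            raise ValueError("n_genes and n_per_cell must be positive")
        universe = set(self.gene_universe())
        for eff in self.stress_effects:
            if not set(eff.genes) <= universe:
                raise ValueError("stress-effect gene set outside gene universe")
        for mod in self.modules:
            if not set(mod.gene_ids) <= universe:
                raise ValueError(f"module {mod.name} outside gene universe")

    def gene_universe(self) -> list:
        width = max(5, len(str(self.n_genes)))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class SimTruth:
    """Everything the generator planted, keyed for downstream recovery checks."""

    de_genes_by_contrast: dict = field(default_factory=dict)
    attribution: dict = field(default_factory=dict)     # gene -> gonadal/genetic/both
    module_assignment: dict = field(default_factory=dict)
    coherence_plan: dict = field(default_factory=dict)  # (regA,regB,sex) -> sets

    def to_json(self) -> str:
        def _conv(obj):
            if isinstance(obj, dict):
                return {str(k): _conv(v) for k, v in obj.items()}
            if isinstance(obj, (set, tuple, list)):
                return [_conv(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        payload = {
            "de_genes_by_contrast": _conv(self.de_genes_by_contrast),
            "attribution": _conv(self.attribution),
            "module_assignment": _conv(self.module_assignment),
            "coherence_plan": {"|".join(k): {kk: sorted(vv) for kk, vv in v.items()}
                               for k, v in self.coherence_plan.items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(config: SimConfig) -> pd.DataFrame:
    """One row per sample over the full genotype x stress x region grid."""
    config.validate()
    rows = []
    for region in config.regions:
        for genotype in config.genotypes:
            for stress in ("ctrl", "stress"):
                for rep in range(1, config.n_per_cell + 1):
                    rows.append({
                        "sample_id": f"{region}_{genotype}_{stress}_r{rep}",
                        "genotype": genotype,
                        "stress": stress,
                        "region": region,
                    })
    return validate_design(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _log2_noise_var(mu0: np.ndarray, phi: np.ndarray,
                    lam: np.ndarray) -> np.ndarray:
    """log2-scale counting-noise variance of NB(mu0 * 2**(lam*z), phi).

    Gamma-Poisson decomposition: the gamma mixing contributes the trigamma
    of 1/phi to Var(ln X); the Poisson part contributes roughly E[1/rate],
    inflated by the lognormal latent factor (capped to keep the fixed
    point bounded for very low-count genes).
    """
    from scipy.special import polygamma
    infl = np.minimum(np.exp((lam * _LN2) ** 2 / 2.0), 10.0)
    gamma_part = polygamma(1, 1.0 / phi)
    poisson_part = infl / (mu0 * np.maximum(1.0 - phi, 0.5))
    return (gamma_part + poisson_part) / _LN2 ** 2


def _module_loading(mu0: np.ndarray, phi: np.ndarray, rho: float,
                    n_iter: int = 8) -> np.ndarray:
    """Latent-factor loading that yields pairwise correlation ``rho``.

    With no idiosyncratic Gaussian term, the counting noise plays that
    role, so lam_g^2 = rho/(1-rho) * sigma_g^2 where sigma_g^2 is the
    gene's log2-scale noise variance; solved by fixed-point iteration
    because sigma_g itself grows with the loading.
    """
    lam = np.zeros_like(mu0, dtype=float)
    for _ in range(n_iter):
        s2 = _log2_noise_var(mu0, phi, lam)
        lam = np.sqrt(rho / (1.0 - rho) * s2)
    return lam


def _draw_dispersions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.dispersion is None:
        return np.exp(rng.uniform(np.log(0.05), np.log(0.5), config.n_genes))
    if np.isscalar(config.dispersion):
        return np.full(config.n_genes, float(config.dispersion))
    disp = np.asarray(config.dispersion, dtype=float)
    if disp.shape != (config.n_genes,):
        raise ValueError("per-gene dispersion length mismatch")
    return disp


def simulate_counts(config: SimConfig,
                    design: pd.DataFrame) -> tuple[CountMatrix, SimTruth]:
    """Draw negative-binomial counts with all planted structure applied."""
    config.validate()
    design = validate_design(design)
    rng = np.random.default_rng(config.seed)
    genes = np.asarray(config.gene_universe(), dtype=object)
    G, S = config.n_genes, len(design)
    gene_index = {g: i for i, g in enumerate(genes)}

    lo, hi = config.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, G)
    phi = _draw_dispersions(config, rng)
    lib = np.exp(rng.uniform(np.log(config.lib_size_range[0]),
                             np.log(config.lib_size_range[1]), S))

    truth = SimTruth()
    module_genes: set = set()
    for mod in config.modules:
        for g in mod.gene_ids:
            truth.module_assignment[g] = mod.name
            module_genes.add(g)

    # ---- planted sex effects (sampled outside module genes) ---------------
    free = np.array([g for g in genes if g not in module_genes], dtype=object)
    n_gon = int(np.floor(config.de_frac_gonadal * G))
    n_gen = int(np.floor(config.de_frac_genetic * G))
    n_both = int(np.floor(config.de_frac_both * G))
    if n_gon + n_gen + n_both > len(free):
        raise ValueError("too few non-module genes for requested DE fractions")
    picked = rng.choice(len(free), n_gon + n_gen + n_both, replace=False)
    sex_genes = free[picked]
    signs = rng.choice([-1.0, 1.0], sex_genes.size)
    gonadal_eff = np.zeros(G)
    genetic_eff = np.zeros(G)
    for k, g in enumerate(sex_genes):
        e = signs[k] * config.sex_effect_size
        i = gene_index[g]
        if k < n_gon:
            truth.attribution[g] = "gonadal"
            gonadal_eff[i] = e
        elif k < n_gon + n_gen:
            truth.attribution[g] = "genetic"
            genetic_eff[i] = e
        else:
            truth.attribution[g] = "both"
            gonadal_eff[i] = e
            genetic_eff[i] = e

    truth.de_genes_by_contrast["sex_XXF_vs_XYM"] = {
        g: gonadal_eff[gene_index[g]] + genetic_eff[gene_index[g]]
        for g in sex_genes}
    truth.de_genes_by_contrast["gonadal_F_vs_M"] = {
        g: gonadal_eff[gene_index[g]] for g in sex_genes
        if gonadal_eff[gene_index[g]] != 0}
    truth.de_genes_by_contrast["genetic_XX_vs_XY"] = {
        g: genetic_eff[gene_index[g]] for g in sex_genes
        if genetic_eff[gene_index[g]] != 0}

    # ---- planted stress effects ------------------------------------------
    stress_eff_maps: dict = {}
    for eff in config.stress_effects:
        regions = [eff.region] if eff.region else list(config.regions)
        sexes = [eff.sex] if eff.sex else ["F", "M"]
        for region in regions:
            for sex in sexes:
                m = stress_eff_maps.setdefault((region, sex), {})
                for g in eff.genes:
                    m[g] = m.get(g, 0.0) + eff.log2_effect
    for (region, sex), m in stress_eff_maps.items():
        truth.de_genes_by_contrast[f"stress_{region}_{sex}"] = dict(m)

    # coherence plan: per region pair and sex, concordant / discordant genes
    for sex in ("F", "M"):
        regs = list(config.regions)
        for a in range(len(regs)):
            for b in range(a + 1, len(regs)):
                ma = stress_eff_maps.get((regs[a], sex), {})
                mb = stress_eff_maps.get((regs[b], sex), {})
                shared = set(ma) & set(mb)
                conc = {g for g in shared if ma[g] * mb[g] > 0}
                disc = {g for g in shared if ma[g] * mb[g] < 0}
                if shared:
                    truth.coherence_plan[(regs[a], regs[b], sex)] = {
                        "concordant": conc, "discordant": disc}

    # ---- mean structure ---------------------------------------------------
    log2mu = np.tile(baseline[:, None], (1, S))
    gon_f = (design["gonadal_sex"] == "F").to_numpy()
    gen_xx = (design["genetic_sex"] == "XX").to_numpy()
    log2mu += gonadal_eff[:, None] * gon_f[None, :]
    log2mu += genetic_eff[:, None] * gen_xx[None, :]

    stressed = (design["stress"] == "stress").to_numpy()
    for (region, sex), m in stress_eff_maps.items():
        cols = (stressed & (design["region"] == region).to_numpy()
                & (design["gonadal_sex"] == sex).to_numpy())
        if not cols.any():
            continue
        for g, e in m.items():
            log2mu[gene_index[g], cols] += e

    # ---- module latent factors -------------------------------------------
    mu0 = 2.0 ** baseline
    # the latent factor is standardized within each (stress, sex, region)
    # cell: the realized within-module correlation then matches the request
    # even at small n, and realized latent means cannot masquerade as
    # stress- or region-DE in downstream contrasts
    cell_ids = (design["stress"].astype(str) + "|"
                + design["gonadal_sex"].astype(str) + "|"
                + design["region"].astype(str)).to_numpy()
    for mod in config.modules:
        z = rng.standard_normal(S)
        for cell in np.unique(cell_ids):
            m = cell_ids == cell
            if m.sum() >= 3 and z[m].std() > 0:
                z[m] = (z[m] - z[m].mean()) / z[m].std()
        rows = np.array([gene_index[g] for g in mod.gene_ids])
        rho = np.array([mod.cor_for(st, sx) for st, sx in
                        zip(design["stress"], design["gonadal_sex"])])
        lam = np.zeros((rows.size, S))
        for r in np.unique(rho):
            if r == 0:
                continue
            cols = rho == r
            lam[:, cols] = _module_loading(mu0[rows], phi[rows], r)[:, None]
        log2mu[rows, :] += lam * z[None, :]

    # ---- negative-binomial draw ------------------------------------------
    mu = 2.0 ** log2mu * lib[None, :]
    r = 1.0 / phi
    p = r[:, None] / (r[:, None] + mu)
    counts = rng.negative_binomial(np.broadcast_to(r[:, None], mu.shape), p)
    cm = CountMatrix(genes, counts, design["sample_id"].to_numpy(dtype=object))
    return cm, truth


# ---------------------------------------------------------------------------
# generator self-validation
# ---------------------------------------------------------------------------

def planted_module_cor_check(counts: CountMatrix, design: pd.DataFrame,
                             truth: SimTruth) -> pd.DataFrame:
    """Realized mean within-module pairwise correlation per condition.

    Correlations are computed on log2-CPM within each (stress, gonadal sex)
    sample group, pooling regions; used to confirm the latent-factor
    loadings hit their targets.
    """
    design = validate_design(design)
    expr = log_cpm(counts)
    frame = expr.to_frame()
    modules: dict = {}
    for g, m in truth.module_assignment.items():
        modules.setdefault(m, []).append(g)
    rows = []
    for name, genes in sorted(modules.items()):
        sub_all = frame.loc[sorted(genes)]
        for (stress, sex), dsub in design.groupby(["stress", "gonadal_sex"],
                                                  sort=True):
            vals = sub_all[dsub["sample_id"]].to_numpy()
            if vals.shape[0] < 2:
                raise ValueError(f"module {name} has fewer than 2 genes")
            c = np.corrcoef(vals)
            iu = np.triu_indices(c.shape[0], k=1)
            rows.append({"module": name, "stress": stress, "gonadal_sex": sex,
                         "n_genes": vals.shape[0], "n_samples": vals.shape[1],
                         "mean_cor": float(np.nanmean(c[iu]))})
    return pd.DataFrame(rows)
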