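"""Synthetic aged-brain cohort and expression generator.

Emulates the statistical structure of a four-region (hippocampus, temporal
cortex, parietal cortex, forebrain white matter), ~107-donor postmortem
cohort in which RNA integrity (RIN) is systematically lower in dementia
donors, about half of all genes covary with RIN, a subset of genes is
sex-bimodal, co-expressed gene blocks share latent factors, and a small
planted set of genes genuinely differs with dementia.  The generator
records every planted coefficient, so parameter-recovery and
confound-removal claims can be tested against ground truth.

All randomness flows from a single integer seed; donors, samples and each
region's expression matrix use fixed sub-seed offsets so each piece is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .enrich import GeneList

REGIONS = ("HIP", "TCx", "PCx", "FWM")

# sub-seed offsets for the per-piece random streams
_DONOR_STREAM = 1
_SAMPLE_STREAM = 2
_GENE_STREAM = 3
_LATENT_STREAM = 4
_REGION_STREAM_BASE = 10


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort and generative-model parameters.

    Defaults mirror the study conditions: 106 donors of whom ~47% have
    dementia, sample RIN ~0.7 lower in dementia donors, half of genes
    RIN-responsive, and a small planted dementia effect.  The ordinal
    pathology scores are generated from ordered-logit models whose
    calibration constants live in ``_ORDINAL_MODELS`` below.
    """

    n_donors: int = 106
    dementia_fraction: float = 0.47
    rin_mean_control: float = 6.9
    rin_delta_dementia: float = 0.7
    rin_sd: float = 1.0
    rin_bounds: tuple[float, float] = (3.0, 10.0)
    frac_rin_genes: float = 0.5
    frac_de_genes: float = 0.008
    frac_sex_genes: float = 0.02
    n_modules: int = 5
    module_size: int = 50
    genes: int = 5000
    noise_sd: float = 0.5
    seed: int = 0
    # effect-size calibration constants (log2 scale unless noted).
    # RIN responsiveness is two-tier: a minority of genes degrade strongly
    # (transcript-stability outliers), the rest respond mildly.
    de_effect_log2: float = 1.4
    rin_strong_frac: float = 0.25
    rin_effect_strong: float = 1.75
    rin_effect_strong_sd: float = 0.3
    # a gene at the detection floor cannot exhibit a large log-scale
    # degradation slope, so strong responders need a minimum baseline
    rin_strong_min_baseline: float = 4.0
    rin_effect_weak: float = 0.1
    rin_effect_weak_sd: float = 0.04
    rin_effect_positive_frac: float = 0.75
    rin_quad_sd: float = 0.02
    # dense donor-level latent factors: broad biological-state variation
    # (cell composition, agonal state) loading weakly on every gene.  The
    # chance group-aligned component of each factor is damped so that the
    # planted DE set stays the only systematic dementia difference;
    # dense_imbalance_factor = 1 would leave the natural sampling imbalance.
    n_dense_factors: int = 30
    dense_loading_sd: float = 0.155
    dense_imbalance_factor: float = 0.88
    sex_effect_log2: float = 2.5
    region_effect_sd: float = 0.4
    module_loading: float = 0.9
    baseline_shape: float = 3.0
    baseline_scale: float = 1.4
    allow_de_rin_overlap: bool = False
    # emulate FPKM's compositional nature by equalizing per-sample totals
    depth_normalize: bool = True

    def __post_init__(self) -> None:
        if self.n_donors < 0:
            raise ValueError(f"n_donors must be >= 0, got {self.n_donors}")
        for name in ("dementia_fraction", "frac_rin_genes", "frac_de_genes",
                     "frac_sex_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genes < 1:
            raise ValueError("genes must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.rin_bounds[0] >= self.rin_bounds[1]:
            raise ValueError("rin_bounds must be increasing")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# Ordered-logit calibration for the ordinal pathology scores: latent =
# slope*dementia + Logistic(0, scale); score = #{cutpoint < latent}.
# Cutpoints are (k + 0.5 - control_mean); scale sets the control-group SD
# (logistic SD = scale*pi/sqrt(3)).  Calibrated so the defaults roughly
# reproduce the cohort's control/dementia group means.
_ORDINAL_MODELS = {
    # name: (levels, control_mean, scale, dementia_slope)
    "braak_stage": (7, 2.8, 0.83, 1.45),
    "cerad_score": (4, 1.2, 0.50, 0.70),
    "nia_reagan": (5, 1.4, 0.39, 0.55),
}


def _ordered_logit(rng, name: str, dementia: np.ndarray) -> np.ndarray:
    levels, ctrl_mean, scale, slope = _ORDINAL_MODELS[name]
    latent = slope * dementia + rng.logistic(0.0, scale, size=dementia.size)
    cuts = np.arange(levels - 1) + 0.5 - ctrl_mean
    return (latent[:, None] > cuts[None, :]).sum(axis=1)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Truncated normal draws by inverse-CDF, vectorized over `mean`."""
    from scipy.stats import norm

    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    a = norm.cdf((lo - mean) / sd)
    b = norm.cdf((hi - mean) / sd)
    u = rng.uniform(a, b)
    return mean + sd * norm.ppf(u)


def _donor_latent_inflammation(config: SimulationConfig) -> np.ndarray:
    """Per-donor inflammation latent, shared by pathology and expression."""
    rng = np.random.default_rng([config.seed, _LATENT_STREAM])
    return rng.standard_normal(config.n_donors)


def _donor_dense_latents(config: SimulationConfig) -> np.ndarray:
    """Donor-level biological-state latents behind the dense loadings."""
    rng = np.random.default_rng([config.seed, _LATENT_STREAM + 1])
    return rng.standard_normal((config.n_donors, config.n_dense_factors))


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate donor and sample tables.

    Donors carry demographics, dementia/AD status, APOE e4 count, ordinal
    pathology staging and cognition; each donor contributes one sample per
    brain region with a RIN draw whose mean is ``rin_delta_dementia`` lower
    for dementia donors, plus non-negative local pathology metrics.
    """
    n = config.n_donors
    rng = np.random.default_rng([config.seed, _DONOR_STREAM])
    donor_ids = [f"D{i + 1:04d}" for i in range(n)]
    dementia = rng.random(n) < config.dementia_fraction
    ad = dementia & (rng.random(n) < 0.6)
    male = rng.random(n) < 0.594
    age = np.round(_truncated_normal(rng, 89.5, 6.5, 77, 102, n)).astype(int)
    education = np.clip(np.round(rng.normal(15 - 0.7 * dementia, 3.0)), 0, None).astype(int)
    apoe_carrier = rng.random(n) < (0.13 + 0.16 * dementia)
    apoe4 = np.where(apoe_carrier, 1 + (rng.random(n) < 0.15), 0).astype(int)
    braak = _ordered_logit(rng, "braak_stage", dementia.astype(float))
    cerad = _ordered_logit(rng, "cerad_score", dementia.astype(float))
    nia = _ordered_logit(rng, "nia_reagan", dementia.astype(float))
    casi = rng.normal(np.where(dementia, -1.2, 0.2), np.where(dementia, 0.8, 0.6))
    num_tbi = np.minimum(rng.poisson(0.65, n), 3)
    donors = pd.DataFrame(
        dict(donor_id=donor_ids, age_at_death=age,
             sex=np.where(male, "M", "F"), dementia=dementia, ad_diagnosis=ad,
             apoe4_alleles=apoe4, braak_stage=braak, cerad_score=cerad,
             nia_reagan=nia, education_years=education,
             casi_irt=casi, num_tbi=num_tbi)
    )

    srng = np.random.default_rng([config.seed, _SAMPLE_STREAM])
    infl = _donor_latent_inflammation(config)
    lo, hi = config.rin_bounds
    rows = []
    for r_idx, region in enumerate(REGIONS):
        rin_mean = config.rin_mean_control - config.rin_delta_dementia * dementia
        rin = _truncated_normal(srng, rin_mean, config.rin_sd, lo, hi, n)
        batch = srng.integers(1, 5, size=n)
        # local pathology: log-normal around the donor's ordinal staging /
        # inflammation latent, with regional multipliers (tau higher in HIP)
        tau_mult = 1.5 if region == "HIP" else 1.0
        at8 = tau_mult * np.exp(0.6 * (braak - 3) + srng.normal(0, 0.7, n))
        ab = np.exp(0.8 * (cerad - 1.2) + srng.normal(0, 0.7, n))
        gfap = np.exp(0.8 * infl + srng.normal(0, 0.5, n))
        iba1 = np.exp(0.7 * infl + srng.normal(0, 0.5, n))
        for i in range(n):
            rows.append(
                dict(sample_id=f"{donor_ids[i]}_{region}", donor_id=donor_ids[i],
                     region=region, rin=rin[i], batch=int(batch[i]),
                     at8_ihc_density=at8[i], ab6e10_ihc_density=ab[i],
                     gfap_ihc_density=gfap[i], iba1_ihc_density=iba1[i])
            )
    samples = pd.DataFrame(rows)
    return donors, samples


def _plant_genes(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-gene ground-truth coefficients."""
    g = config.genes
    rng = np.random.default_rng([config.seed, _GENE_STREAM])
    gene_ids = [f"g{i + 1:05d}" for i in range(g)]
    baseline = rng.gamma(config.baseline_shape, config.baseline_scale, g)
    region_off = rng.normal(0.0, config.region_effect_sd, (g, len(REGIONS)))

    n_rin = int(round(config.frac_rin_genes * g))
    rin_idx = rng.choice(g, n_rin, replace=False)
    rin_lin = np.zeros(g)
    sign = np.where(rng.random(n_rin) < config.rin_effect_positive_frac, 1.0, -1.0)
    eligible_strong = baseline[rin_idx] >= config.rin_strong_min_baseline
    n_strong = min(int(round(config.rin_strong_frac * n_rin)), int(eligible_strong.sum()))
    strong = np.zeros(n_rin, dtype=bool)
    if n_strong:
        strong[rng.choice(np.flatnonzero(eligible_strong), n_strong, replace=False)] = True
    mag = np.where(
        strong,
        np.abs(rng.normal(config.rin_effect_strong, config.rin_effect_strong_sd, n_rin)),
        np.abs(rng.normal(config.rin_effect_weak, config.rin_effect_weak_sd, n_rin)),
    )
    rin_lin[rin_idx] = sign * np.maximum(mag, 0.02)
    rin_quad = np.zeros(g)
    rin_quad[rin_idx] = rng.normal(0.0, config.rin_quad_sd, n_rin)

    de_pool = np.arange(g) if config.allow_de_rin_overlap else np.setdiff1d(np.arange(g), rin_idx)
    n_de = int(round(config.frac_de_genes * g))
    if n_de > de_pool.size:
        raise ValueError("not enough genes free of RIN effects for the requested DE set")
    de_idx = rng.choice(de_pool, n_de, replace=False)
    beta = np.zeros(g)
    beta[de_idx] = np.where(rng.random(n_de) < 0.5, 1.0, -1.0) * config.de_effect_log2

    sex_pool = np.setdiff1d(np.arange(g), de_idx)
    n_sex = int(round(config.frac_sex_genes * g))
    sex_idx = rng.choice(sex_pool, min(n_sex, sex_pool.size), replace=False)
    sex_delta = np.zeros(g)
    sex_delta[sex_idx] = np.where(rng.random(sex_idx.size) < 0.5, 1.0, -1.0) * config.sex_effect_log2

    module_id = np.zeros(g, dtype=int)
    loading = np.zeros(g)
    module_pool = np.setdiff1d(np.arange(g), np.concatenate([de_idx, sex_idx]))
    need = config.n_modules * config.module_size
    if need > module_pool.size:
        raise ValueError("not enough genes for the requested module structure")
    chosen = rng.choice(module_pool, need, replace=False)
    for m in range(config.n_modules):
        members = chosen[m * config.module_size:(m + 1) * config.module_size]
        module_id[members] = m + 1
        loading[members] = config.module_loading * np.where(
            rng.random(members.size) < 0.9, 1.0, -1.0
        )

    dense = rng.normal(0.0, config.dense_loading_sd, (g, config.n_dense_factors))
    gt = pd.DataFrame(
        dict(baseline=baseline, dementia_beta=beta, rin_lin=rin_lin,
             rin_quad=rin_quad, sex_delta=sex_delta, module_id=module_id,
             module_loading=loading, dense_var=(dense**2).sum(axis=1)),
        index=pd.Index(gene_ids, name="gene_id"),
    )
    gt.attrs["dense_loadings"] = dense
    for j, region in enumerate(REGIONS):
        gt[f"mean_{region}"] = baseline + region_off[:, j]
    # inflammation loading: genes of the last module track the donor-level
    # inflammation latent (shared across regions)
    gt["inflammation_loading"] = np.where(module_id == config.n_modules, loading, 0.0)
    return gt


def rin_center(config: SimulationConfig) -> float:
    """Center of the RIN covariate used by the generative model."""
    return config.rin_mean_control - config.dementia_fraction * config.rin_delta_dementia


def generate_expression(
    donors: pd.DataFrame, samples: pd.DataFrame, config: SimulationConfig
):
    """Generate per-region linear-FPKM expression matrices plus ground truth.

    Generative model, in log2(FPKM + 1) space for gene i, sample s of
    region r with donor d::

        x_is = mean_r(i) + sex_delta_i * 1[male_d] + beta_i * 1[dementia_d]
             + b1_i * (RIN_s - c) + b2_i * ((RIN_s - c)^2 - sd_RIN^2)
             + loading_i * factor_{r, module(i)}(s) + eps,   eps ~ N(0, noise_sd)

    where c is the cohort-level RIN center.  The matrix is returned in
    linear space via 2**x - 1 clamped at 0.  The inflammation module's
    factor is the donor-level latent shared across regions; other module
    factors are drawn independently per region.
    """
    from .matrix import LINEAR, ExpressionMatrix

    missing = set(samples["donor_id"]) - set(donors["donor_id"])
    if missing:
        raise ValueError(f"samples reference unknown donors: {sorted(missing)[:3]}")
    gt = _plant_genes(config)
    donor_idx = pd.Index(donors["donor_id"])
    male = (donors["sex"] == "M").to_numpy(dtype=float)
    dem = donors["dementia"].to_numpy(dtype=float)
    infl = _donor_latent_inflammation(config)
    dense_latents = _donor_dense_latents(config)
    if config.n_dense_factors and config.dense_imbalance_factor < 1.0:
        dc = dem - dem.mean()
        denom = float(dc @ dc)
        if denom > 0:
            coef = dense_latents.T @ dc / denom
            dense_latents = dense_latents - (
                (1.0 - config.dense_imbalance_factor) * np.outer(dc, coef)
            )
    c = rin_center(config)
    matrices: dict[str, ExpressionMatrix] = {}
    module_factors: dict[str, dict[int, np.ndarray]] = {}
    for r_idx, region in enumerate(REGIONS):
        reg = samples[samples["region"] == region]
        if reg.empty:
            continue
        rng = np.random.default_rng([config.seed, _REGION_STREAM_BASE + r_idx])
        di = donor_idx.get_indexer(reg["donor_id"])
        rin = reg["rin"].to_numpy(dtype=float)
        x = np.tile(gt[f"mean_{region}"].to_numpy()[:, None], (1, len(reg)))
        x += gt["sex_delta"].to_numpy()[:, None] * male[di][None, :]
        x += gt["dementia_beta"].to_numpy()[:, None] * dem[di][None, :]
        rc = rin - c
        x += gt["rin_lin"].to_numpy()[:, None] * rc[None, :]
        x += gt["rin_quad"].to_numpy()[:, None] * (rc**2 - config.rin_sd**2)[None, :]
        if config.n_dense_factors:
            x += gt.attrs["dense_loadings"] @ dense_latents[di].T
        module_factors[region] = {}
        for m in range(1, config.n_modules + 1):
            members = gt["module_id"].to_numpy() == m
            if not members.any():
                continue
            if m == config.n_modules:
                factor = infl[di]
            else:
                factor = rng.standard_normal(len(reg))
            module_factors[region][m] = factor
            x[members] += gt.loc[members, "module_loading"].to_numpy()[:, None] * factor[None, :]
        x += rng.normal(0.0, config.noise_sd, x.shape)
        linear = np.clip(2.0**x - 1.0, 0.0, None)
        if config.depth_normalize:
            # FPKM is depth-normalized by construction: rescale every sample
            # to the cohort-mean total signal, so degradation shifts
            # composition rather than the column total
            totals = linear.sum(axis=0)
            linear = linear * (totals.mean() / totals)[None, :]
        matrices[region] = ExpressionMatrix(
            pd.DataFrame(linear, index=gt.index, columns=list(reg["sample_id"])),
            space=LINEAR,
        )
    gt.attrs["module_factors"] = module_factors  # realized latents, for tests
    return matrices, gt


def generate_gene_lists(
    ground_truth: pd.DataFrame,
    kind: str,
    direction: str,
    size: int,
    seed: int,
) -> GeneList:
    """Sample an external-style gene list from the planted structure.

    kind: ``dementia`` (planted DE genes), ``degradation`` (RIN-responsive
    genes) or ``null`` (uniform).  ``direction`` selects the sign: for
    dementia lists, up/down refer to expression in dementia vs control;
    for degradation lists, down means lower expression in degraded
    (low-RIN) samples, i.e. a positive RIN coefficient.
    """
    if direction not in ("up", "down", "unsigned"):
        raise ValueError(f"unknown direction: {direction!r}")
    if kind == "dementia":
        col = ground_truth["dementia_beta"]
    elif kind == "degradation":
        col = ground_truth["rin_lin"]
    elif kind == "null":
        col = None
    else:
        raise ValueError(f"unknown kind: {kind!r}")
    if col is None:
        eligible = ground_truth.index
    elif direction == "up":
        eligible = ground_truth.index[col > 0] if kind == "dementia" else ground_truth.index[col < 0]
    elif direction == "down":
        eligible = ground_truth.index[col < 0] if kind == "dementia" else ground_truth.index[col > 0]
    else:
        eligible = ground_truth.index[col != 0]
    if size > len(eligible):
        raise ValueError(f"requested {size} genes but only {len(eligible)} eligible")
    rng = np.random.default_rng(seed)
    genes = tuple(rng.choice(np.asarray(eligible, dtype=object), size, replace=False))
    return GeneList(name=f"{kind}_{direction}_{size}", genes=genes,
                    direction=direction, source=f"synthetic {kind} list")
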