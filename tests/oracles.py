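"""Independent Monte-Carlo oracles for the generative model."""

import numpy as np


def marginal_oracle_fraction(cfg, n_genes, seed):
    """Monte-Carlo of the stated per-gene generative model.

    Re-simulates gene expression against RIN directly from the model
    formula (coefficient tiers, latent variance, noise, depth shift) and
    returns the fraction of genes with |cor(expr, RIN)| > 0.5.
    """
    r = np.random.default_rng(seed)
    n = cfg.n_donors
    dem = r.random(n) < cfg.dementia_fraction
    from rintx.synthetic import _truncated_normal, rin_center
    lo, hi = cfg.rin_bounds
    rin = _truncated_normal(
        r, cfg.rin_mean_control - cfg.rin_delta_dementia * dem, cfg.rin_sd, lo, hi, n
    )
    rc = rin - rin_center(cfg)
    hits = 0
    mean_b1 = cfg.frac_rin_genes * (2 * cfg.rin_effect_positive_frac - 1) * (
        cfg.rin_strong_frac * cfg.rin_effect_strong
        + (1 - cfg.rin_strong_frac) * cfg.rin_effect_weak
    )
    for _ in range(n_genes):
        b1 = 0.0
        if r.random() < cfg.frac_rin_genes:
            if r.random() < cfg.rin_strong_frac:
                b1 = abs(r.normal(cfg.rin_effect_strong, cfg.rin_effect_strong_sd))
            else:
                b1 = abs(r.normal(cfg.rin_effect_weak, cfg.rin_effect_weak_sd))
            if r.random() >= cfg.rin_effect_positive_frac:
                b1 = -b1
        other_var = cfg.noise_sd**2 + cfg.n_dense_factors * cfg.dense_loading_sd**2
        if r.random() < cfg.n_modules * cfg.module_size / cfg.genes:
            other_var += cfg.module_loading**2
        other_sd = np.sqrt(other_var)
        expr = (b1 - mean_b1) * rc + r.normal(0, other_sd, n)
        if abs(np.corrcoef(expr, rin)[0, 1]) > 0.5:
            hits += 1
    return hits / n_genes
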