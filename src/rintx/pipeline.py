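"""End-to-end pipeline runner.

Chains the stages: synthetic-cohort simulation (optional), TbT total-signal
normalization, dementia differential expression on uncorrected data, RIN
correction, differential expression on corrected data, corrected-vs-
uncorrected ranking concordance, co-expression modules with eigengene-trait
association, and the cross-study concordance panel.  Every artifact is
written as plain text with a provenance header (package version, seed,
config hash); identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpress, diffexp, enrich, io, normalize, synthetic
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("tbt", "rin_correct", "de", "modules", "concordance")


@dataclass
class PipelineConfig:
    simulation: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig
    )
    stages: tuple[str, ...] = DEFAULT_STAGES
    regions: tuple[str, ...] = synthetic.REGIONS
    de_params: diffexp.DEParams = field(default_factory=lambda: diffexp.DEParams(correction="bh"))
    rin_params: normalize.RinCorrectionParams = field(
        default_factory=normalize.RinCorrectionParams
    )
    net_params: coexpress.NetworkParams = field(default_factory=coexpress.NetworkParams)
    use_sva: bool = False
    out_dir: str | None = None
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain mapping (e.g. parsed YAML).

    Recognized keys: ``simulation`` (SimulationConfig fields), ``stages``,
    ``regions``, ``use_sva``, ``seed``, ``out_dir`` and the parameter
    blocks ``de_params``, ``rin_params``, ``net_params``.
    """
    kwargs: dict = {}
    if "simulation" in raw:
        kwargs["simulation"] = synthetic.SimulationConfig(**raw["simulation"])
    for key in ("stages", "regions"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    for key in ("use_sva", "seed", "out_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    blocks = dict(de_params=diffexp.DEParams, rin_params=normalize.RinCorrectionParams,
                  net_params=coexpress.NetworkParams)
    for key, cls in blocks.items():
        if key in raw:
            kwargs[key] = cls(**raw[key])
    return PipelineConfig(**kwargs)


def cortex_de_flags(
    matrices: dict[str, ExpressionMatrix], log2fc_cutoff: float = 1.0
) -> pd.Series:
    """Flag genes differing strongly between cortex and non-cortex samples.

    TbT scaling needs a set of genes designated differentially expressed,
    derived here from the cortex (TCx, PCx) vs non-cortex contrast; the
    scaling then uses only the complement.
    """
    cortex, other = [], []
    for region, m in matrices.items():
        log2 = m.to_log2().data
        (cortex if region in ("TCx", "PCx") else other).append(log2.mean(axis=1))
    if not cortex or not other:
        # single-compartment input: no gene is flagged
        any_m = next(iter(matrices.values()))
        return pd.Series(False, index=any_m.gene_ids)
    diff = (pd.concat(cortex, axis=1).mean(axis=1)
            - pd.concat(other, axis=1).mean(axis=1))
    return diff.abs() > log2fc_cutoff


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the artifact bundle.

    The bundle maps artifact names to in-memory objects; when ``out_dir``
    is set each artifact is also written as TSV/CSV with a provenance
    header.  Any stage failure raises with the stage name; artifacts
    completed before the failure are kept on disk.
    """
    bundle: dict = {}
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.as_dict()
    cfg_dict.pop("out_dir", None)  # hash the analysis config, not the destination
    header = io.provenance_header(config.seed, cfg_dict)

    def persist_table(name: str, df: pd.DataFrame) -> None:
        if out is not None:
            io.write_table(df, out / f"{name}.csv", header_lines=header)

    def persist_matrix(name: str, m: ExpressionMatrix) -> None:
        if out is not None:
            io.write_expression(m, out / f"{name}.tsv", header_lines=header)

    stage = "simulate"
    try:
        sim = config.simulation.with_(seed=config.seed)
        donors, samples = synthetic.generate_cohort(sim)
        matrices, ground_truth = synthetic.generate_expression(donors, samples, sim)
        matrices = {r: m for r, m in matrices.items() if r in config.regions}
        bundle.update(donors=donors, samples=samples, ground_truth=ground_truth)
        persist_table("donors", donors)
        persist_table("samples", samples)
        persist_table("ground_truth", ground_truth.reset_index())

        if "tbt" in config.stages:
            stage = "tbt"
            flags = cortex_de_flags(matrices)
            log2 = {}
            for region, m in matrices.items():
                norm, scalars = normalize.tbt_normalize(m, flags.loc[m.gene_ids])
                log2[region] = norm
                bundle[f"scale_factors_{region}"] = scalars
        else:
            log2 = {r: m.to_log2() for r, m in matrices.items()}
        bundle["log2"] = log2
        for region, m in log2.items():
            persist_matrix(f"expression_{region}", m)

        sample_meta = samples.set_index("sample_id")
        dementia_of = donors.set_index("donor_id")["dementia"]

        def groups_for(m: ExpressionMatrix) -> np.ndarray:
            return dementia_of.loc[sample_meta.loc[m.sample_ids, "donor_id"]].to_numpy()

        if "de" in config.stages:
            stage = "de_uncorrected"
            de_unc = {}
            for region, m in log2.items():
                sv = (diffexp.estimate_surrogate_variables(m, groups_for(m), seed=config.seed)
                      if config.use_sva else None)
                de_unc[region] = diffexp.differential_expression(
                    m, groups_for(m), surrogates=sv, params=config.de_params
                )
                persist_table(f"de_uncorrected_{region}", de_unc[region].reset_index())
            bundle["de_uncorrected"] = de_unc

        if "rin_correct" in config.stages:
            stage = "rin_correct"
            corrected, reports = {}, {}
            for region, m in log2.items():
                corr, rep = normalize.rin_correct_matrix(m, samples, config.rin_params)
                corrected[region] = corr
                reports[region] = rep
                persist_matrix(f"corrected_{region}", corr)
                persist_table(f"rin_report_{region}", rep)
            bundle["corrected"] = corrected
            bundle["rin_reports"] = reports
        else:
            corrected = log2

        if "de" in config.stages:
            stage = "de_corrected"
            de_cor = {}
            for region, m in corrected.items():
                sv = (diffexp.estimate_surrogate_variables(m, groups_for(m), seed=config.seed)
                      if config.use_sva else None)
                de_cor[region] = diffexp.differential_expression(
                    m, groups_for(m), surrogates=sv, params=config.de_params
                )
                persist_table(f"de_corrected_{region}", de_cor[region].reset_index())
            bundle["de_corrected"] = de_cor

            stage = "ranking_concordance"
            conc = {}
            for region in corrected:
                rho, p = diffexp.ranking_concordance(
                    bundle["de_uncorrected"][region], de_cor[region]
                )
                conc[region] = dict(spearman_r=rho, p=p)
            bundle["ranking_concordance"] = conc
            persist_table("ranking_concordance",
                          pd.DataFrame(conc).T.rename_axis("region").reset_index())

        if "modules" in config.stages:
            stage = "modules"
            partitions, me_traits = {}, {}
            for region, m in corrected.items():
                reg_samples = samples[samples["region"] == region]
                part = coexpress.build_modules(m, config.net_params, samples=reg_samples)
                part = coexpress.refine_modules(m, part, config.net_params)
                partitions[region] = part
                traits = reg_samples.set_index("sample_id")[
                    ["rin", "at8_ihc_density", "ab6e10_ihc_density",
                     "gfap_ihc_density", "iba1_ihc_density"]
                ]
                me_traits[region] = coexpress.me_trait_association(
                    part.eigengenes, traits
                )
                persist_table(f"modules_{region}",
                              part.labels.rename("module").reset_index())
                persist_table(f"me_trait_{region}", me_traits[region])
            bundle["modules"] = partitions
            bundle["me_trait"] = me_traits

        if "concordance" in config.stages and "de" in config.stages:
            stage = "concordance_panel"
            region = next(iter(corrected))
            rin_vals = sample_meta.loc[corrected[region].sample_ids, "rin"].to_numpy()
            rin_res = diffexp.rin_association(corrected[region], rin_vals)
            metrics = {
                "log2fc_corrected": bundle["de_corrected"][region]["log2_fold_change"],
                "log2fc_uncorrected": bundle["de_uncorrected"][region]["log2_fold_change"],
                "rin_correlation": rin_res["pearson_r"],
            }
            eligible = {
                ("dementia", "up"): int((ground_truth["dementia_beta"] > 0).sum()),
                ("degradation", "down"): int((ground_truth["rin_lin"] > 0).sum()),
                ("null", "unsigned"): len(ground_truth),
            }
            caps = {"dementia": 20, "degradation": 100, "null": 100}
            lists = [
                synthetic.generate_gene_lists(
                    ground_truth, kind, direction, min(caps[kind], n_avail),
                    seed=config.seed + i,
                )
                for i, ((kind, direction), n_avail) in enumerate(eligible.items(), 1)
                if n_avail > 0
            ]
            panel = enrich.concordance_panel(metrics, lists)
            bundle["concordance_panel"] = panel
            persist_table("concordance_panel", panel)
    except Exception as exc:  # annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle
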