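"""RNA-quality-aware normalization.

Two stages.  First, TbT-style total-signal scaling: each sample is
multiplied in linear FPKM space by a scalar derived from the summed
expression of genes designated non-differentially-expressed, then a single
global scalar (found by monotone root-finding) restores the data set's
total log2(FPKM + 1) to its pre-normalization value.

Second, per-gene, per-region RIN correction: zeros and >3 SD outliers are
excluded, the retained log2 values are described by a one- or two-component
Gaussian mixture (chosen by BIC), RIN enters as a quadratic regressor
within each component, and the corrected value is the OLS residual plus the
component mean, with negatives clamped to zero.  Modeling the mixture first
lets genuinely bimodal genes (e.g. sex-linked) keep their bimodality while
the within-component RIN trend is removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

from .matrix import LINEAR, LOG2, ExpressionMatrix

logger = logging.getLogger(__name__)


class DegenerateSampleError(ValueError):
    """A sample's non-DE signal sums to zero; it cannot be TbT-scaled."""


def tbt_normalize(
    matrix: ExpressionMatrix, de_flags: pd.Series | np.ndarray
) -> tuple[ExpressionMatrix, pd.Series]:
    """Total-signal scaling conserving the summed log2(FPKM + 1).

    ``de_flags`` marks genes considered differentially expressed; scaling
    uses only the complement.  Stage 1 multiplies each sample (in linear
    space) by mean(non-DE sums) / (its own non-DE sum); stage 2
    log2-transforms; stage 3 applies one further global linear-space scalar
    chosen by root-finding so the total log2(FPKM + 1) matches the input's
    to relative tolerance 1e-9.

    Returns the log2-space matrix and the composite per-sample scalars.
    """
    if matrix.space != LINEAR:
        raise ValueError("tbt_normalize expects a linear-FPKM matrix")
    flags = np.asarray(de_flags, dtype=bool)
    if flags.shape[0] != matrix.shape[0]:
        raise ValueError("de_flags length must match gene count")
    if flags.all():
        raise ValueError("at least one gene must be flagged non-DE")
    x = matrix.data.to_numpy(dtype=float)
    non_de_sums = x[~flags].sum(axis=0)
    zero = np.flatnonzero(non_de_sums == 0)
    if zero.size:
        raise DegenerateSampleError(
            f"sample {matrix.sample_ids[zero[0]]!r} has zero non-DE signal"
        )
    stage1 = non_de_sums.mean() / non_de_sums
    scaled = x * stage1[None, :]
    target = np.log2(x + 1.0).sum()

    def total(c: float) -> float:
        return np.log2(c * scaled + 1.0).sum() - target

    # total(c) is strictly increasing in c; bracket around 1
    lo, hi = 0.5, 2.0
    while total(lo) > 0:
        lo /= 2.0
    while total(hi) < 0:
        hi *= 2.0
    c = brentq(total, lo, hi, xtol=1e-15, rtol=1e-14)
    out = np.log2(c * scaled + 1.0)
    result = ExpressionMatrix(
        pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids),
        space=LOG2,
    )
    scalars = pd.Series(stage1 * c, index=matrix.sample_ids, name="scale_factor")
    return result, scalars


@dataclass(frozen=True)
class RinCorrectionParams:
    outlier_sd: float = 3.0
    min_points_per_component: int = 8
    polynomial_degree: int = 2
    clamp_at_zero: bool = True
    # k=2 must beat k=1 by this BIC margin.  Mixture selection by raw BIC
    # over-splits skewed or trend-broadened unimodal data; demanding
    # decisive evidence restricts two components to well-separated modes
    # (genuine bimodality, e.g. sex-linked genes, exceeds this easily).
    bic_margin: float = 30.0

    def __post_init__(self) -> None:
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be > 0")
        if self.polynomial_degree < 1:
            raise ValueError("polynomial_degree must be >= 1")


@dataclass
class MixtureFit:
    """Mixture description of one gene's retained expression values."""

    k: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    assignment: np.ndarray       # component index per retained sample
    retained: np.ndarray         # indices into the original vector
    excluded: np.ndarray         # zeros and outliers
    criterion_values: dict[int, float] = field(default_factory=dict)
    skipped: bool = False


def _exclusions(values: np.ndarray, params: RinCorrectionParams):
    nonzero = values != 0
    if nonzero.sum() >= 2:
        mu = values[nonzero].mean()
        sd = values[nonzero].std(ddof=1)
        outlier = nonzero & (np.abs(values - mu) > params.outlier_sd * sd) if sd > 0 else np.zeros_like(nonzero)
    else:
        outlier = np.zeros_like(nonzero)
    retained = np.flatnonzero(nonzero & ~outlier)
    excluded = np.flatnonzero(~(nonzero & ~outlier))
    return retained, excluded


def select_mixture_components(
    values: np.ndarray, params: RinCorrectionParams = RinCorrectionParams()
) -> MixtureFit:
    """Describe a gene's retained values by one or two Gaussians.

    Zeros and >``outlier_sd``-SD outliers are excluded first.  Candidates
    are a single Gaussian and two-component mixtures with tied or free
    variances (fit by EM); the winner is chosen by BIC, with ties within
    ``bic_margin`` resolved to the single component.  Fewer than
    2 x ``min_points_per_component`` retained values force k = 1; fewer
    than 3 mark the gene as skipped (returned uncorrected downstream).
    """
    values = np.asarray(values, dtype=float)
    retained, excluded = _exclusions(values, params)
    x = values[retained]
    if x.size < 3:
        return MixtureFit(k=1, means=np.array([x.mean() if x.size else 0.0]),
                          variances=np.array([0.0]), weights=np.array([1.0]),
                          assignment=np.zeros(x.size, dtype=int),
                          retained=retained, excluded=excluded, skipped=True)
    mu, var = x.mean(), max(x.var(), 1e-12)
    n = x.size
    bic1 = n * np.log(2 * np.pi * var) + n + 2 * np.log(n)  # -2LL + params*ln(n)
    crit = {1: float(bic1)}
    if n < 2 * params.min_points_per_component or np.ptp(x) == 0:
        return MixtureFit(k=1, means=np.array([mu]), variances=np.array([var]),
                          weights=np.array([1.0]),
                          assignment=np.zeros(n, dtype=int),
                          retained=retained, excluded=excluded,
                          criterion_values=crit)
    best2 = None
    xr = x.reshape(-1, 1)
    for cov in ("tied", "full"):
        gm = GaussianMixture(n_components=2, covariance_type=cov,
                             random_state=0, n_init=1, reg_covar=1e-6)
        gm.fit(xr)
        bic = gm.bic(xr)
        if best2 is None or bic < best2[0]:
            best2 = (bic, gm)
    crit[2] = float(best2[0])
    if best2[0] < bic1 - params.bic_margin:
        gm = best2[1]
        assign = gm.predict(xr)
        # a component smaller than the guard is likely a likelihood spike,
        # and could not support the quadratic fit anyway
        if min(np.bincount(assign, minlength=2)) >= params.min_points_per_component:
            means = gm.means_.ravel()
            if gm.covariance_type == "tied":
                variances = np.full(2, float(np.ravel(gm.covariances_)[0]))
            else:
                variances = gm.covariances_.ravel()
            return MixtureFit(k=2, means=means, variances=variances,
                              weights=gm.weights_.ravel(), assignment=assign,
                              retained=retained, excluded=excluded,
                              criterion_values=crit)
    return MixtureFit(k=1, means=np.array([mu]), variances=np.array([var]),
                      weights=np.array([1.0]), assignment=np.zeros(n, dtype=int),
                      retained=retained, excluded=excluded, criterion_values=crit)


def rin_correct_gene(
    values: np.ndarray,
    rin: np.ndarray,
    params: RinCorrectionParams = RinCorrectionParams(),
    fit: MixtureFit | None = None,
) -> np.ndarray:
    """Remove the within-component quadratic RIN trend from one gene.

    Within each mixture component, expression is regressed on
    (RIN, RIN^2) by OLS and replaced by residual + component mean of the
    retained values.  Outliers are excluded from the fit but still
    corrected with their nearest component's model (their RIN values lie
    inside the fitted support, and passing them through would leave
    high-leverage RIN signal in the output); zeros keep their original
    value.  Negatives are clamped to zero.
    """
    values = np.asarray(values, dtype=float)
    rin = np.asarray(rin, dtype=float)
    if values.shape != rin.shape:
        raise ValueError("values and rin must have equal length")
    if fit is None:
        fit = select_mixture_components(values, params)
    out = values.copy()
    if fit.skipped:
        return out
    degree = params.polynomial_degree
    outliers = np.array([i for i in fit.excluded if values[i] != 0], dtype=int)
    for comp in range(fit.k):
        idx = fit.retained[fit.assignment == comp]
        if idx.size < degree + 2:
            logger.warning("component %d has %d points (< %d); left uncorrected",
                           comp, idx.size, degree + 2)
            continue
        r = rin[idx]
        design = np.vander(r, degree + 1, increasing=True)  # 1, r, r^2
        y = values[idx]
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        out[idx] = resid + y.mean()
        if outliers.size:
            # nonzero outliers: detrend with the nearest component's fit
            if fit.k == 1:
                mine = outliers
            else:
                d = np.abs(values[outliers][:, None] - fit.means[None, :])
                mine = outliers[d.argmin(axis=1) == comp]
            if mine.size:
                pred = np.vander(rin[mine], degree + 1, increasing=True) @ coef
                out[mine] = values[mine] - pred + y.mean()
    if params.clamp_at_zero:
        np.clip(out, 0.0, None, out=out)
    return out


def rin_correct_matrix(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    params: RinCorrectionParams = RinCorrectionParams(),
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Apply the per-gene RIN correction within each region partition.

    ``samples`` must carry ``sample_id``, ``region`` and ``rin`` for every
    matrix column.  Returns the corrected matrix (dimensions unchanged) and
    a per-(gene, region) report with the chosen component count, exclusion
    counts, skip flag and pre/post Pearson correlation with RIN.
    """
    if matrix.space != LOG2:
        raise ValueError("rin_correct_matrix expects log2(FPKM + 1) values")
    meta = samples.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples table missing entries for {missing[:3]}")
    sub = meta.loc[matrix.sample_ids]
    if sub["rin"].isna().any():
        bad = sub.index[sub["rin"].isna()][0]
        raise ValueError(f"missing RIN for sample {bad!r}")
    out = matrix.data.to_numpy(dtype=float).copy()
    report_rows = []
    cols = matrix.sample_ids
    for region, reg in sub.groupby("region", sort=False):
        col_idx = cols.get_indexer(reg.index)
        rin = reg["rin"].to_numpy(dtype=float)
        for gi, gene in enumerate(matrix.gene_ids):
            vals = out[gi, col_idx]
            fit = select_mixture_components(vals, params)
            corrected = rin_correct_gene(vals, rin, params, fit=fit)
            out[gi, col_idx] = corrected
            report_rows.append(
                dict(gene_id=gene, region=region, k=fit.k,
                     n_excluded=len(fit.excluded), skipped=fit.skipped,
                     pre_rin_cor=_safe_cor(vals, rin),
                     post_rin_cor=_safe_cor(corrected, rin))
            )
    result = ExpressionMatrix(
        pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids),
        space=LOG2,
    )
    return result, pd.DataFrame(report_rows)


def _safe_cor(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])
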