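"""Differential expression and variance partitioning.

Per-region dementia-vs-control differential expression by gene-wise linear
models with optional surrogate variables (hidden-structure covariates
estimated from the residual matrix by SVD with a parallel-analysis rank
rule), per-gene RIN association screening, Spearman concordance of
corrected vs uncorrected fold-change rankings, greedy matched-subcohort
construction, and permutation distance-matrix regression (MDMR) for
variance explained by a single covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import LOG2, ExpressionMatrix


@dataclass(frozen=True)
class DEParams:
    """Thresholds for calling a gene differentially expressed.

    ``fc_threshold`` is on the fold scale (1.3 means |log2FC| > log2 1.3);
    set ``fc_on_log2_scale`` to interpret it directly as a log2FC cutoff.
    """

    fc_threshold: float = 1.3
    p_threshold: float = 0.05
    correction: str = "none"  # none | bh | bonferroni
    fc_on_log2_scale: bool = False

    def __post_init__(self) -> None:
        if self.fc_threshold <= (0.0 if self.fc_on_log2_scale else 1.0):
            raise ValueError("fc_threshold out of range")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.correction not in ("none", "bh", "bonferroni"):
            raise ValueError(f"unknown correction: {self.correction!r}")

    @property
    def log2fc_cutoff(self) -> float:
        return self.fc_threshold if self.fc_on_log2_scale else float(np.log2(self.fc_threshold))


def _as_log2_values(matrix) -> tuple[np.ndarray, pd.Index, pd.Index]:
    if isinstance(matrix, ExpressionMatrix):
        if matrix.space != LOG2:
            raise ValueError("expected a log2(FPKM + 1) matrix")
        df = matrix.data
    else:
        df = matrix
    return df.to_numpy(dtype=float), df.index, df.columns


def estimate_surrogate_variables(
    matrix, primary_variable, n_perm: int = 20, seed: int = 0
) -> np.ndarray:
    """Estimate hidden-structure covariates orthogonal to the primary variable.

    The primary variable is regressed out of every gene; the number of
    surrogate dimensions q is the number of leading singular values of the
    residual matrix exceeding the 95th percentile of the corresponding
    singular values obtained after independently permuting each residual
    row (a parallel-analysis rule).  The returned samples x q matrix holds
    the top-q right singular vectors, residualized against the primary
    variable and the intercept, then re-normalized.
    """
    y, _, sample_ids = _as_log2_values(matrix)
    v = np.asarray(primary_variable, dtype=float)
    if v.shape[0] != y.shape[1]:
        raise ValueError("primary_variable length must equal sample count")
    n = y.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples")
    x = np.column_stack([np.ones(n), v])
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y - (x @ beta).T
    # residual rows live in the orthogonal complement of span(1, primary);
    # express them in an orthonormal basis of that subspace so row-wise
    # permutation stays within the same geometry as the observed matrix
    q_full, _ = np.linalg.qr(x, mode="complete")
    basis = q_full[:, x.shape[1]:]
    coords = resid @ basis  # genes x (n - 2)
    sv = np.linalg.svd(coords, compute_uv=False)
    rng = np.random.default_rng(seed)
    k = min(10, len(sv))
    perm_sv = np.empty((n_perm, k))
    for p in range(n_perm):
        shuf = coords.copy()
        rng.permuted(shuf, axis=1, out=shuf)
        perm_sv[p] = np.linalg.svd(shuf, compute_uv=False)[:k]
    thresh = np.percentile(perm_sv, 95, axis=0)
    q = 0
    for i in range(k):
        if sv[i] > thresh[i]:
            q += 1
        else:
            break
    if q == 0:
        return np.empty((n, 0))
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    sur = vt[:q].T  # samples x q
    # orthogonalize against [1, primary]
    proj, *_ = np.linalg.lstsq(x, sur, rcond=None)
    sur = sur - x @ proj
    norms = np.linalg.norm(sur, axis=0)
    keep = norms > 1e-12
    sur = sur[:, keep] / norms[keep]
    return sur


def differential_expression(
    matrix, group_labels, surrogates: np.ndarray | None = None,
    params: DEParams = DEParams(),
) -> pd.DataFrame:
    """Gene-wise linear-model test of a two-group contrast.

    Fits expression ~ intercept + group (+ surrogates) per gene; the
    reported p comes from the group coefficient's t-statistic, while
    ``log2_fold_change`` is the raw difference of group means in log2
    space (not covariate-adjusted), keeping the fold-change axis
    independent of the significance engine.  BH and Bonferroni columns
    are always populated.  Constant genes get p = 1, log2FC = 0.
    """
    y, gene_ids, sample_ids = _as_log2_values(matrix)
    g = np.asarray(group_labels).astype(bool)
    if g.shape[0] != y.shape[1]:
        raise ValueError("group_labels length must equal sample count")
    n1, n0 = int(g.sum()), int((~g).sum())
    if min(n1, n0) < 2:
        raise ValueError("each group needs at least 2 samples")
    cols = [np.ones(y.shape[1]), g.astype(float)]
    names = ["intercept", "group"]
    if surrogates is not None and np.size(surrogates):
        sur = np.atleast_2d(np.asarray(surrogates, dtype=float))
        if sur.shape[0] != y.shape[1]:
            sur = sur.T
        for j in range(sur.shape[1]):
            cols.append(sur[:, j])
            names.append(f"sv{j + 1}")
    x = np.column_stack(cols)
    n, p = x.shape
    dof = n - p
    if dof < 1:
        raise ValueError("not enough samples for the design")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv.T                      # genes x p
    resid = y - beta @ x.T
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[:, 1] / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    constant = y.std(axis=1) == 0
    pvals[constant] = 1.0
    lfc = y[:, g].mean(axis=1) - y[:, ~g].mean(axis=1)
    lfc[constant] = 0.0
    out = pd.DataFrame(
        dict(log2_fold_change=lfc, statistic=t, p=pvals,
             p_bh=multipletests(pvals, method="fdr_bh")[1],
             p_bonf=np.minimum(pvals * len(pvals), 1.0)),
        index=gene_ids,
    )
    out.attrs["n_per_group"] = (n0, n1)
    out.attrs["covariates_used"] = names[2:]
    return out


def count_de_genes(result: pd.DataFrame, params: DEParams = DEParams()) -> tuple[int, int]:
    """Count genes passing the fold-change and p thresholds, by direction."""
    p_col = {"none": "p", "bh": "p_bh", "bonferroni": "p_bonf"}[params.correction]
    passing = (result[p_col] < params.p_threshold) & (
        result["log2_fold_change"].abs() > params.log2fc_cutoff
    )
    n_up = int((passing & (result["log2_fold_change"] > 0)).sum())
    n_down = int((passing & (result["log2_fold_change"] < 0)).sum())
    return n_up, n_down


def rin_association(matrix, rin) -> pd.DataFrame:
    """Per-gene Pearson correlation with RIN and two-sided p.

    Constant genes are flagged ``assessable = False`` with NaN statistics
    and are excluded from the BH denominator.
    """
    y, gene_ids, _ = _as_log2_values(matrix)
    r_vec = np.asarray(rin, dtype=float)
    if r_vec.shape[0] != y.shape[1]:
        raise ValueError("rin length must equal sample count")
    n = y.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    ys = y - y.mean(axis=1, keepdims=True)
    rs = r_vec - r_vec.mean()
    denom = np.sqrt((ys**2).sum(axis=1) * (rs**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, ys @ rs / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    assessable = ~np.isnan(r)
    p_bh = np.full_like(p, np.nan)
    if assessable.any():
        p_bh[assessable] = multipletests(p[assessable], method="fdr_bh")[1]
    return pd.DataFrame(
        dict(pearson_r=r, p=np.where(assessable, p, np.nan), p_bh=p_bh,
             assessable=assessable),
        index=gene_ids,
    )


def ranking_concordance(result_a: pd.DataFrame, result_b: pd.DataFrame):
    """Spearman correlation of two fold-change orderings on shared genes."""
    shared = result_a.index.intersection(result_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    rho, p = stats.spearmanr(
        result_a.loc[shared, "log2_fold_change"],
        result_b.loc[shared, "log2_fold_change"],
    )
    return float(rho), float(p)


def mdmr_variance_explained(
    matrix, covariate, n_perm: int = 100, seed: int = 0
) -> tuple[float, float, float]:
    """Distance-matrix regression of samples on one covariate.

    Sample-sample distances are 1 - Pearson r over genes; the Gower-centered
    inner-product matrix is decomposed against the hat matrix of the
    univariate design [1, covariate], giving a pseudo-F, the fraction of
    distance variance explained, and an add-one permutation p-value.
    """
    y, _, _ = _as_log2_values(matrix)
    v = np.asarray(covariate, dtype=float)
    n = y.shape[1]
    if v.shape[0] != n:
        raise ValueError("covariate length must equal sample count")
    if np.ptp(v) == 0:
        raise ValueError("covariate is constant")
    d = 1.0 - np.corrcoef(y.T)
    np.fill_diagonal(d, 0.0)
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    gower = j @ a @ j
    trace_total = np.trace(gower)

    def pseudo_f(cov: np.ndarray) -> tuple[float, float]:
        x = np.column_stack([np.ones(n), cov])
        h = x @ np.linalg.pinv(x)
        ss_model = np.trace(h @ gower @ h)
        ss_resid = trace_total - ss_model
        m = 1
        f = (ss_model / m) / (ss_resid / (n - m - 1))
        return f, ss_model / trace_total

    f_obs, frac = pseudo_f(v)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_perm, _ = pseudo_f(rng.permutation(v))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return float(f_obs), float(frac), float(p)


def match_subcohort(
    donors: pd.DataFrame,
    samples: pd.DataFrame,
    match_on: tuple[str, ...] = ("rin", "sex"),
    balance: str = "dementia",
) -> pd.DataFrame:
    """Greedy 1:1 RIN matching of case and control donors within sex strata.

    Donor-level RIN is the mean over that donor's samples.  Within each sex
    stratum, cross-group donor pairs are taken greedily in order of
    |RIN difference| without replacement.  Returns the matched pairs with
    their RIN gap; the result's ``attrs`` record the matched and full-cohort
    group mean differences.
    """
    if "rin" not in match_on:
        raise ValueError("match_on must include 'rin'")
    rin = samples.groupby("donor_id")["rin"].mean()
    d = donors.set_index("donor_id")
    d = d.join(rin.rename("mean_rin"))
    grp = d[balance].astype(bool)
    if grp.all() or not grp.any():
        raise ValueError("both groups must be non-empty")
    strata = d.groupby("sex").groups if "sex" in match_on else {"all": d.index}
    pairs = []
    for stratum, idx in strata.items():
        sub = d.loc[idx]
        cases = sub.index[sub[balance].astype(bool)]
        ctrls = sub.index[~sub[balance].astype(bool)]
        if len(cases) == 0 or len(ctrls) == 0:
            warnings.warn(f"stratum {stratum!r} has only one group; skipped")
            continue
        cand = [
            (abs(sub.at[a, "mean_rin"] - sub.at[b, "mean_rin"]), a, b)
            for a in cases for b in ctrls
        ]
        cand.sort(key=lambda t: (t[0], t[1], t[2]))
        used_a, used_b = set(), set()
        for dist, a, b in cand:
            if a in used_a or b in used_b:
                continue
            used_a.add(a)
            used_b.add(b)
            pairs.append(dict(stratum=stratum, case=a, control=b, rin_gap=dist))
    out = pd.DataFrame(pairs)
    if not out.empty:
        matched = d.loc[list(out["case"]), "mean_rin"].mean() - d.loc[
            list(out["control"]), "mean_rin"
        ].mean()
    else:
        matched = np.nan
    full = d.loc[grp, "mean_rin"].mean() - d.loc[~grp, "mean_rin"].mean()
    out.attrs["matched_rin_gap"] = float(matched) if matched == matched else np.nan
    out.attrs["full_rin_gap"] = float(full)
    return out
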