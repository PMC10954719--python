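"""Condition dependence of pile-up sites from replicated count data.

Raw 5'-start counts per candidate locus are compared between knockout and
control libraries with the standard count-data toolkit: trimmed-mean-of-
M-values (TMM) normalisation of library sizes, negative-binomial dispersion
estimation with empirical-Bayes shrinkage toward a common value, a
per-locus likelihood-ratio test of the condition effect, and
Benjamini-Hochberg FDR control.  A site is called dependent when its
knockout-vs-control log2 fold change is below -1.5 at FDR < 0.05 (loss
only; a two-sided variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "tmm_factors",
    "estimate_dispersions",
    "fit_and_test",
    "call_dependent",
    "call_dependent_and_intersect",
    "LOG2FC_CUT",
    "FDR_CUT",
]

LOG2FC_CUT = -1.5
FDR_CUT = 0.05


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed mean of M-values normalisation factors, geometric mean 1.

    The reference library is the one whose upper quartile of nonzero
    relative counts is closest to the mean upper quartile.  Per library,
    M (log2 relative-count ratio to the reference) and A (average log2
    abundance) are doubly trimmed and the precision-weighted mean of M
    gives the log2 factor.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat.sum(axis=0) == 0).any():
        lib = counts.columns[int(np.flatnonzero(mat.sum(axis=0) == 0)[0])]
        raise ValueError(f"library {lib!r} has all-zero counts")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    libs = library_sizes.to_numpy(dtype=float)

    rel = mat / libs
    uq = np.array([
        np.quantile(col[col > 0], 0.75) if (col > 0).any() else 0.0
        for col in rel.T
    ])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    log2_factors = np.zeros(mat.shape[1])
    for k in range(mat.shape[1]):
        if k == ref_idx:
            continue
        log2_factors[k] = _tmm_pair(
            mat[:, k], libs[k], mat[:, ref_idx], libs[ref_idx], trim_m, trim_a
        )
    factors = 2.0 ** log2_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(y, n, y_ref, n_ref, trim_m, trim_a):
    keep = (y > 0) & (y_ref > 0)
    if keep.sum() == 0:
        return 0.0
    y, y_ref = y[keep], y_ref[keep]
    m = np.log2((y / n) / (y_ref / n_ref))
    a = 0.5 * np.log2((y / n) * (y_ref / n_ref))
    # delta-method variance of M; weights are its inverse
    var = (n - y) / (n * y) + (n_ref - y_ref) / (n_ref * y_ref)

    if np.allclose(m, m[0]):
        return float(m[0]) if np.isfinite(m[0]) else 0.0
    n_obs = len(m)
    lo_m, hi_m = np.floor(n_obs * trim_m) + 1, n_obs + 1 - (np.floor(n_obs * trim_m) + 1)
    lo_a, hi_a = np.floor(n_obs * trim_a) + 1, n_obs + 1 - (np.floor(n_obs * trim_a) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep2.sum() == 0:
        return 0.0
    w = 1.0 / var[keep2]
    return float(np.sum(w * m[keep2]) / np.sum(w))


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def _nb_loglik(y, mu, alpha):
    """Negative binomial log likelihood, mean/dispersion parametrisation
    (variance = mu + alpha mu^2)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-10)
    if alpha <= 0:
        return float(np.sum(stats.poisson.logpmf(np.round(y), mu)))
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )
    )


def estimate_dispersions(
    counts: np.ndarray,
    eff_lib: np.ndarray,
    groups: np.ndarray,
    prior_df: float = 10.0,
) -> tuple[float, np.ndarray]:
    """Common dispersion by pooled profile likelihood on equalised counts,
    then per-locus method-of-moments estimates shrunk toward it.

    Counts are scaled to a common (geometric-mean) effective library size;
    group means are profiled out as sample means.  Shrinkage weight is
    ``prior_df`` against the per-locus residual degrees of freedom.
    """
    geo = np.exp(np.mean(np.log(eff_lib)))
    pseudo = counts * (geo / eff_lib)

    labels = np.unique(groups)
    group_masks = [groups == g for g in labels]

    def neg_pooled(log_alpha):
        # Cox-Reid adjusted profile likelihood: penalise by half the log
        # information of each profiled group mean, which removes the
        # downward bias of the plug-in mean at small replicate numbers
        alpha = float(np.exp(log_alpha))
        total = 0.0
        for mask in group_masks:
            block = pseudo[:, mask]
            mu = np.maximum(block.mean(axis=1, keepdims=True), 1e-8)
            total += _nb_loglik(block, np.broadcast_to(mu, block.shape), alpha)
            info = (mu[:, 0] * mask.sum()) / (1.0 + alpha * mu[:, 0])
            total -= 0.5 * float(np.log(info).sum())
        return -total

    res = optimize.minimize_scalar(
        neg_pooled, bounds=(np.log(1e-6), np.log(10.0)), method="bounded"
    )
    common = float(np.exp(res.x))

    # per-locus method of moments on the pseudo counts, pooled across groups
    n = counts.shape[1]
    df_resid = n - len(labels)
    mom = np.zeros(counts.shape[0])
    for mask in group_masks:
        block = pseudo[:, mask]
        mu = block.mean(axis=1)
        s2 = block.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = (s2 - mu) / np.maximum(mu, 1e-10) ** 2
        mom += np.where(np.isfinite(contrib), contrib, 0.0)
    mom = np.maximum(mom / len(labels), 0.0)

    shrunk = (prior_df * common + df_resid * mom) / (prior_df + df_resid)
    return common, shrunk


# ---------------------------------------------------------------------------
# per-locus NB likelihood-ratio test
# ---------------------------------------------------------------------------

def _nb_group_mean(y, eff, alpha, tol=1e-10, max_iter=50):
    """MLE of a common rate m with means m * eff under fixed dispersion."""
    y = np.asarray(y, float)
    eff = np.asarray(eff, float)
    m = max(y.sum() / eff.sum(), 1e-12)
    if alpha <= 0:
        return m  # Poisson MLE is exact
    # Newton iteration in log m: score = sum (y-mu)/(1+alpha mu),
    # expected information = sum mu/(1+alpha mu)
    for _ in range(max_iter):
        mu = m * eff
        denom = 1.0 + alpha * mu
        score = np.sum((y - mu) / denom)
        info = np.sum(mu / denom)
        if info <= 0:
            break
        step = np.clip(score / info, -5, 5)
        m *= np.exp(step)
        if abs(step) < tol:
            break
    return m


def _nb_group_mean_vec(Y, eff, alphas, tol=1e-10, max_iter=60):
    """Row-wise MLE of a common rate m with means m * eff, fixed dispersion."""
    Y = np.asarray(Y, float)
    m = np.maximum(Y.sum(axis=1) / eff.sum(), 1e-12)
    a = alphas[:, None]
    for _ in range(max_iter):
        mu = m[:, None] * eff[None, :]
        denom = 1.0 + a * mu
        score = ((Y - mu) / denom).sum(axis=1)
        info = np.maximum((mu / denom).sum(axis=1), 1e-12)
        step = np.clip(score / info, -5.0, 5.0)
        m = m * np.exp(step)
        if np.abs(step).max() < tol:
            break
    return m


def _nb_loglik_rows(Y, MU, alphas):
    """Per-row NB log likelihood (variance = mu + alpha mu^2)."""
    Y = np.asarray(Y, float)
    MU = np.maximum(MU, 1e-10)
    r = (1.0 / alphas)[:, None]
    return (
        special.gammaln(Y + r) - special.gammaln(r) - special.gammaln(Y + 1)
        + r * np.log(r / (r + MU)) + Y * np.log(MU / (r + MU))
    ).sum(axis=1)


def fit_and_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    design: pd.Series | dict,
    library_sizes: pd.Series | None = None,
    prior_df: float = 10.0,
    two_sided_gate: bool = False,
) -> pd.DataFrame:
    """Per-locus NB likelihood-ratio test of the condition effect.

    ``design`` maps library name to "control" or "knockout"; at least two
    replicates per condition are required.  Returns a frame with log2FC
    (knockout vs control), p, BH fdr and the dependent flag under the
    log2FC < -1.5 & FDR < 0.05 gate (or |log2FC| > 1.5 when
    ``two_sided_gate``).  All-zero loci are excluded before testing.
    """
    design = pd.Series(design)
    design = design.loc[counts.columns]
    for cond in ("control", "knockout"):
        if (design == cond).sum() < 2:
            raise ValueError(f"need >= 2 {cond} replicates to estimate dispersion")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    eff = (library_sizes.loc[counts.columns] * factors.loc[counts.columns]).to_numpy(
        dtype=float
    )

    keep = counts.sum(axis=1) > 0
    mat = counts.loc[keep].to_numpy(dtype=float)
    groups = (design == "knockout").to_numpy().astype(int)

    common, alphas = estimate_dispersions(mat, eff, groups, prior_df=prior_df)

    ctrl = groups == 0
    ko = groups == 1
    alphas = np.maximum(alphas, 1e-8)
    m_ctrl = _nb_group_mean_vec(mat[:, ctrl], eff[ctrl], alphas)
    m_ko = _nb_group_mean_vec(mat[:, ko], eff[ko], alphas)
    m_all = _nb_group_mean_vec(mat, eff, alphas)
    ll_full = _nb_loglik_rows(mat[:, ctrl], m_ctrl[:, None] * eff[ctrl], alphas)
    ll_full += _nb_loglik_rows(mat[:, ko], m_ko[:, None] * eff[ko], alphas)
    ll_null = _nb_loglik_rows(mat, m_all[:, None] * eff, alphas)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    pvals = stats.chi2.sf(lrt, df=1)
    log2fc = np.log2(np.maximum(m_ko, 1e-12) / np.maximum(m_ctrl, 1e-12))

    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "dispersion": alphas,
        },
        index=counts.index[keep],
    )
    out["dependent"] = call_dependent(out, two_sided=two_sided_gate)
    out.attrs["common_dispersion"] = common
    return out


def call_dependent(
    results: pd.DataFrame,
    lfc_cut: float = LOG2FC_CUT,
    fdr_cut: float = FDR_CUT,
    two_sided: bool = False,
) -> pd.Series:
    """Apply the fold-change / FDR gate (loss-only by default)."""
    if two_sided:
        fc_ok = results["log2fc"].abs() > abs(lfc_cut)
    else:
        fc_ok = results["log2fc"] < lfc_cut
    return fc_ok & (results["fdr"] < fdr_cut)


def call_dependent_and_intersect(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame | None = None,
    **gate_kwargs,
) -> dict:
    """Dependent-site index sets for one or two analyses plus intersection."""
    dep_a = set(results_a.index[call_dependent(results_a, **gate_kwargs)])
    out = {"A": dep_a}
    if results_b is not None:
        dep_b = set(results_b.index[call_dependent(results_b, **gate_kwargs)])
        out["B"] = dep_b
        out["intersection"] = dep_a & dep_b
    return out
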