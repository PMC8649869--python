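"""Two-group negative-binomial differential expression.

The model: counts for gene *g* in sample *j* are NB-distributed with mean
``mu_gj`` and variance ``mu + phi * mu**2``. Samples are library-size
normalized by median-of-ratios factors; per-gene dispersions come from a
method-of-moments estimate shrunk toward the across-gene mean; the test is
a likelihood-ratio test of a shared NB mean against free per-group means at
fixed dispersion, referred to chi-square with one degree of freedom. The
result table carries the log2 fold change of group B over group A
(pseudocount 0.5), the raw p-value, and its Benjamini–Hochberg adjustment.

Genes significant at p < 0.05 with |log2FC| >= 0.58 (a 1.5-fold change) are
classed as differentially regulated; the raw-p filter is the default, with
an FDR-based variant available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .errors import ValidationError
from .matrix import CountMatrix
from .multitest import bh_adjust

P_MAX = 0.05
MIN_ABS_LFC = 0.58
DISPERSION_PRIOR_DF = 20.0
_TINY_MU = 1e-10


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample scale factors (geometric-mean reference).

    The reference profile is the per-gene geometric mean over samples,
    computed on genes positive in every sample; each sample's factor is the
    median of its ratios to the reference, centred so factors multiply to 1.
    """
    vals = counts.values.to_numpy(dtype=float)
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no gene is positive in all samples; filter low-coverage genes first"
        )
    ref = np.exp(np.log(vals[positive]).mean(axis=1))
    factors = np.median(vals[positive] / ref[:, None], axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.values.columns, name="size_factor")


def normalize_by_size_factors(counts: CountMatrix) -> CountMatrix:
    """Divide each sample by its median-of-ratios factor."""
    sf = size_factors(counts)
    values = counts.values.astype(float) / sf
    return CountMatrix(values=values, samples=counts.samples.copy(), normalized=True)


def _group_moments(vals: np.ndarray, group_cols: list[np.ndarray]):
    means, variances, dfs = [], [], []
    for cols in group_cols:
        y = vals[:, cols]
        if y.shape[1] >= 2:
            means.append(y.mean(axis=1))
            variances.append(y.var(axis=1, ddof=1))
            dfs.append(y.shape[1] - 1)
    return means, variances, dfs


def estimate_dispersion(
    counts: CountMatrix,
    groups: dict[str, list[str]],
    shrinkage: float | None = None,
    prior_df: float = DISPERSION_PRIOR_DF,
) -> pd.Series:
    """Per-gene NB dispersion, method-of-moments with common-value shrinkage.

    Within each group with >= 2 replicates, ``phi = (var - mean) / mean**2``
    (floored at 0); group estimates are pooled by degrees of freedom, then
    shrunk toward the across-gene mean raw dispersion:
    ``phi = (1 - w) * phi_raw + w * phi_common``.

    By default the weight is precision-dependent,
    ``w = prior_df / (prior_df + residual_df)``, so noisy per-gene estimates
    at few replicates lean almost entirely on the common value (which keeps
    the downstream test calibrated) while well-replicated designs retain
    gene-specific dispersion. Pass an explicit ``shrinkage`` float in
    [0, 1] to fix the weight instead.
    """
    if counts.values.shape[1] < 2:
        raise ValidationError("dispersion estimation needs at least two samples")
    col_index = {s: i for i, s in enumerate(counts.values.columns)}
    group_cols = []
    for name, samples in groups.items():
        counts.require_samples(samples)
        group_cols.append(np.array([col_index[s] for s in samples]))
    vals = counts.values.to_numpy(dtype=float)
    means, variances, dfs = _group_moments(vals, group_cols)
    if not dfs:
        raise ValidationError("no group has >= 2 replicates")
    num = np.zeros(vals.shape[0])
    den = np.zeros(vals.shape[0])
    for m, v, df in zip(means, variances, dfs):
        ok = m > 0
        num[ok] += df * (v[ok] - m[ok])
        den[ok] += df * m[ok] ** 2
    raw = np.zeros(vals.shape[0])
    nz = den > 0
    raw[nz] = np.maximum(0.0, num[nz] / den[nz])
    common = float(raw.mean())
    if shrinkage is None:
        residual_df = float(sum(dfs))
        shrinkage = prior_df / (prior_df + residual_df)
    if not (0.0 <= shrinkage <= 1.0):
        raise ValidationError("shrinkage weight must lie in [0, 1]")
    shrunk = (1.0 - shrinkage) * raw + shrinkage * common
    return pd.Series(shrunk, index=counts.values.index, name="dispersion")


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood summed over samples; Poisson at phi = 0.

    ``y``: (genes, samples); ``mu``: broadcastable to y; ``phi``: (genes,).
    Non-integer y (normalized counts) enters through the gamma function.
    """
    mu = np.maximum(mu, _TINY_MU)
    phi = np.asarray(phi, dtype=float)
    out = np.empty(y.shape[0])
    pois = phi <= 0
    if pois.any():
        yp, mp = y[pois], mu[pois]
        out[pois] = (yp * np.log(mp) - mp - gammaln(yp + 1.0)).sum(axis=1)
    nb = ~pois
    if nb.any():
        r = (1.0 / phi[nb])[:, None]
        yn, mn = y[nb], mu[nb]
        ll = (
            gammaln(yn + r)
            - gammaln(r)
            - gammaln(yn + 1.0)
            + r * np.log(r / (r + mn))
            + yn * np.log(mn / (r + mn))
        )
        out[nb] = ll.sum(axis=1)
    return out


def nb_test(
    counts: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    dispersion: pd.Series,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Likelihood-ratio test of equal NB means between two groups.

    ``counts`` must be normalized. For each gene the shared-mean null is
    compared with free per-group means at the gene's fixed dispersion; the
    statistic is referred to chi-square (1 df). Genes with all-zero counts
    are dropped before testing. Returns a DataFrame indexed by gene with
    columns ``base_mean``, ``log2fc`` (B over A), ``pvalue``, ``padj``.
    """
    if not counts.normalized:
        raise ValidationError("nb_test requires a normalized matrix")
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    counts.require_samples(list(group_a) + list(group_b))
    phi = dispersion.reindex(counts.values.index)
    if phi.isna().any():
        raise ValidationError("dispersion missing for some genes")
    ya = counts.values[list(group_a)].to_numpy(dtype=float)
    yb = counts.values[list(group_b)].to_numpy(dtype=float)
    nonzero = (ya.sum(axis=1) + yb.sum(axis=1)) > 0
    ya, yb = ya[nonzero], yb[nonzero]
    phi_arr = phi.to_numpy(dtype=float)[nonzero]
    genes = counts.values.index[nonzero]

    mean_a = ya.mean(axis=1)
    mean_b = yb.mean(axis=1)
    n_a, n_b = ya.shape[1], yb.shape[1]
    mean_0 = (ya.sum(axis=1) + yb.sum(axis=1)) / (n_a + n_b)

    ll_alt = _nb_loglik(ya, mean_a[:, None], phi_arr) + _nb_loglik(
        yb, mean_b[:, None], phi_arr
    )
    ll_null = _nb_loglik(np.hstack([ya, yb]), mean_0[:, None], phi_arr)
    stat = np.maximum(0.0, 2.0 * (ll_alt - ll_null))
    pvalue = chi2.sf(stat, df=1)
    pvalue = np.clip(pvalue, np.finfo(float).tiny, 1.0)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    result = pd.DataFrame(
        {
            "base_mean": (mean_a * n_a + mean_b * n_b) / (n_a + n_b),
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
        },
        index=pd.Index(genes, name="gene"),
    )
    return result


def filter_de(
    results: pd.DataFrame,
    p_max: float = P_MAX,
    min_abs_lfc: float = MIN_ABS_LFC,
    use_fdr: bool = False,
) -> dict[str, set[str]]:
    """Partition genes into up/down sets by the significance filter.

    The boundary semantics are strict on p (p must be smaller than
    ``p_max``; p equal to the cutoff is excluded) and inclusive on the fold
    change (``|log2fc| >= min_abs_lfc``).
    """
    if results.empty:
        raise ValidationError("empty DE result table")
    p = results["padj"] if use_fdr else results["pvalue"]
    sig = p < p_max
    up = set(results.index[sig & (results["log2fc"] >= min_abs_lfc)])
    down = set(results.index[sig & (results["log2fc"] <= -min_abs_lfc)])
    return {"up": up, "down": down}
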