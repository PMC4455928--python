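"""RNA-seq differential expression between yolk-depleted and sham embryos.

The caller composes five steps: an expression filter (maximal read count
must exceed a threshold), median-of-ratios library-size normalization, a
self-contained conditioned negative-binomial exact test with moment-based
binned-shrinkage dispersion, Benjamini-Hochberg correction with selection at
FDR < 0.05, and a replicate-consistency rule that keeps a gene only when the
normalized YD - SP difference carries the same non-zero sign in every batch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, DE_TABLE_COLUMNS, DesignError, validate_de_table

DEFAULT_MAX_COUNT = 5
DEFAULT_FDR = 0.05


def filter_max_count(cm: CountMatrix, threshold: int = DEFAULT_MAX_COUNT) -> CountMatrix:
    """Keep genes whose maximal count over all samples strictly exceeds
    ``threshold``; a gene maxing at exactly the threshold is dropped."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = cm.counts.max(axis=1) > threshold
    return CountMatrix(cm.counts.loc[keep], cm.sample_meta)


def normalize_libsize(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean over samples; genes with a
    zero in any sample are excluded from the reference (their log ratio is
    undefined).
    """
    counts = cm.counts.to_numpy(dtype=float)
    if np.any(counts.sum(axis=0) <= 0):
        raise ValueError("every sample needs a positive total count")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene is nonzero in all samples")
    logc = np.log(counts[positive])
    log_ref = logc.mean(axis=1)
    log_factors = np.median(logc - log_ref[:, None], axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=cm.counts.columns, name="size_factor")


def _moment_dispersions(q: np.ndarray, yd: np.ndarray, sp: np.ndarray,
                        n_bins: int = 20) -> np.ndarray:
    """Binned-shrinkage moment estimate of the NB dispersion per gene.

    Per gene the within-condition pooled variance gives the raw moment
    estimate (var - mu) / mu^2; raw values (possibly negative) are averaged
    within abundance bins before flooring, so sampling noise does not inflate
    the shared estimate.
    """
    mu = q.mean(axis=1)
    parts, dofs = [], 0
    for cols in (yd, sp):
        if cols.sum() >= 2:
            parts.append(((q[:, cols] - q[:, cols].mean(axis=1, keepdims=True)) ** 2)
                         .sum(axis=1))
            dofs += cols.sum() - 1
    if dofs == 0:
        return np.full(q.shape[0], 0.1)
    var = sum(parts) / dofs
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mu) / mu**2
    raw[~np.isfinite(raw)] = 0.0

    order = np.argsort(mu, kind="stable")
    n = len(mu)
    n_bins = max(1, min(n_bins, n // 50)) if n >= 50 else 1
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    disp = np.empty(n)
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = order[lo:hi]
        disp[idx] = max(raw[idx].mean(), 1e-8)
    return disp


def _exact_nb_p(a: int, s: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditioned NB exact p-value.

    Conditions on the total ``s`` of the two (rounded, normalized) group
    sums; group sums are NB with mean ``n_g * mu0`` and dispersion
    ``phi / n_g``.  The p-value sums the conditional probabilities of all
    outcomes no more likely than the observed split (minimum-likelihood
    two-sided rule, as in exact NB testing).
    """
    if s == 0:
        return 1.0
    mu0 = s / (n_a + n_b)
    size_a, size_b = n_a / phi, n_b / phi
    mu_a, mu_b = n_a * mu0, n_b * mu0

    if s <= 20000:
        x = np.arange(s + 1)
    else:  # evaluate only where mass is non-negligible, plus the observed split
        sd = np.sqrt(mu_a + phi / n_a * mu_a**2)
        lo = max(0, int(mu_a - 25 * sd))
        hi = min(s, int(mu_a + 25 * sd))
        x = np.arange(lo, hi + 1)
        if a < lo or a > hi:
            x = np.concatenate([x, [a]])
    logw = (stats.nbinom.logpmf(x, size_a, size_a / (size_a + mu_a))
            + stats.nbinom.logpmf(s - x, size_b, size_b / (size_b + mu_b)))
    w = np.exp(logw - logw.max())
    w_obs = w[x == a][0]
    p = w[w <= w_obs * (1 + 1e-10)].sum() / w.sum()
    return float(min(max(p, 1e-300), 1.0))


def nb_exact_test(cm: CountMatrix, size_factors: pd.Series) -> pd.DataFrame:
    """Per-gene raw p-values and log2 YD/SP effects.

    Effects use a 0.5 pseudocount on the normalized group means.  Genes with
    zero counts everywhere get p = 1 and effect 0.
    """
    yd_cols = cm.counts.columns.isin(cm.samples_of("YD"))
    sp_cols = cm.counts.columns.isin(cm.samples_of("SP"))
    if yd_cols.sum() < 1 or sp_cols.sum() < 1:
        raise DesignError("need at least one sample per condition")

    q = cm.counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    disp = _moment_dispersions(q, yd_cols, sp_cols)

    mean_yd = q[:, yd_cols].mean(axis=1)
    mean_sp = q[:, sp_cols].mean(axis=1)
    effect = np.log2((mean_yd + 0.5) / (mean_sp + 0.5))

    sum_yd = np.rint(q[:, yd_cols].sum(axis=1)).astype(np.int64)
    sum_sp = np.rint(q[:, sp_cols].sum(axis=1)).astype(np.int64)
    n_a, n_b = int(yd_cols.sum()), int(sp_cols.sum())

    p = np.ones(cm.n_genes)
    for i in range(cm.n_genes):
        s = sum_yd[i] + sum_sp[i]
        if s > 0:
            p[i] = _exact_nb_p(int(sum_yd[i]), int(s), n_a, n_b, disp[i])
    return pd.DataFrame(
        {"gene_id": cm.gene_ids, "p_raw": p, "score": effect}
    ).set_index("gene_id", drop=False)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order.

    adjusted[i] = min over ranks j >= rank(i) of  p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted_sorted, 1.0)
    return out


def consistency_filter(cm: CountMatrix, candidates: pd.DataFrame,
                       size_factors: pd.Series | None = None) -> pd.DataFrame:
    """Demote candidates whose normalized YD - SP difference changes sign
    (or is zero) in any batch; never promotes a gene."""
    if size_factors is None:
        size_factors = normalize_libsize(cm)
    q = cm.counts / size_factors

    meta = cm.sample_meta
    diffs = []
    for batch, grp in meta.groupby("batch"):
        yd = grp.index[grp["condition"] == "YD"]
        sp = grp.index[grp["condition"] == "SP"]
        if len(yd) != 1 or len(sp) != 1:
            raise DesignError(f"batch {batch!r} is not a YD/SP pair")
        diffs.append(q[yd[0]] - q[sp[0]])
    sign = np.sign(np.column_stack(diffs))
    consistent = (np.abs(sign.sum(axis=1)) == sign.shape[1])
    consistent = pd.Series(consistent, index=cm.gene_ids)

    out = candidates.copy()
    keep = out["gene_id"].map(consistent).fillna(False).astype(bool)
    out["passed"] = out["passed"] & keep.to_numpy()
    return out


def call_rnaseq_de(cm: CountMatrix, fdr_threshold: float = DEFAULT_FDR,
                   max_count_threshold: int = DEFAULT_MAX_COUNT) -> pd.DataFrame:
    """Full RNA-seq DE caller for one time point.

    Returns the shared DE-table schema (gene_id, score, p_raw, fdr,
    direction, passed); ``passed`` requires FDR strictly below the threshold
    and per-batch sign consistency.
    """
    filtered = filter_max_count(cm, max_count_threshold)
    if filtered.n_genes == 0:
        return validate_de_table(pd.DataFrame(columns=DE_TABLE_COLUMNS))
    factors = normalize_libsize(filtered)
    res = nb_exact_test(filtered, factors)
    res["fdr"] = bh_adjust(res["p_raw"].to_numpy())
    res["direction"] = np.where(res["score"] >= 0, "up_in_YD", "down_in_YD")
    res["passed"] = res["fdr"] < fdr_threshold
    res = consistency_filter(filtered, res, factors)
    return validate_de_table(res[DE_TABLE_COLUMNS].reset_index(drop=True))
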