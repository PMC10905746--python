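"""Negative-binomial exact testing for differential occupancy and expression.

The same machinery serves two jobs: differential occupancy at peaks
(wild type vs knockout, with spike-in derived effective library sizes as
offsets) and differential expression (knockout vs wild type, and the
wild-type differentiation trajectory D0/D3/D6).

The test is a sum-conditional NB exact test with a common dispersion phi:
counts are rescaled to a common pseudo-library size, summed within groups,
and the group sums are modelled as

    Y_a ~ NB(n_a * mu, phi / n_a),   Y_b ~ NB(n_b * mu, phi / n_b),

(a sum of n i.i.d. NB(mu, phi) variables with a shared success probability
is NB(n*mu, phi/n)).  Conditional on the total ``n = y_a + y_b`` the law of
``Y_a`` does not depend on mu, so the two-sided p-value is computed by
enumerating all outcomes ``y in 0..n`` and summing the conditional
probabilities not exceeding that of the observed outcome (the "minlike"
convention).  At phi = 0 this reduces to the conditional binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class DispersionEstimate:
    """Common NB dispersion (squared coefficient of biological variation)."""

    phi: float

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("dispersion must be >= 0")


def _geometric_mean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.exp(np.mean(np.log(x))))


def estimate_common_dispersion(
    counts: np.ndarray,
    lib_sizes: np.ndarray,
    groups: np.ndarray,
    min_mean: float = 5.0,
) -> DispersionEstimate:
    """Method-of-moments common dispersion.

    Counts are rescaled to the geometric-mean library size; per feature,
    ``phi_f = max(0, (s^2 - m) / m^2)`` with ``m`` the overall rescaled mean
    and ``s^2`` the within-group pooled variance; the common phi is the
    median of ``phi_f`` over features with ``m > min_mean``.
    """
    counts = np.asarray(counts, dtype=float)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    groups = np.asarray(groups)
    scaled = counts * (_geometric_mean(lib_sizes) / lib_sizes)[None, :]
    m = scaled.mean(axis=1)
    ss = np.zeros(len(counts))
    dof = 0
    for g in np.unique(groups):
        sub = scaled[:, groups == g]
        if sub.shape[1] < 2:
            continue
        ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
        dof += sub.shape[1] - 1
    if dof == 0:
        raise ValueError("need >= 2 replicates in at least one group")
    s2 = ss / dof
    keep = m > min_mean
    if not keep.any():
        raise ValueError(f"no feature exceeds the mean-count filter ({min_mean})")
    phi_f = np.maximum(0.0, (s2[keep] - m[keep]) / m[keep] ** 2)
    return DispersionEstimate(float(np.median(phi_f)))


def _conditional_log_pmf(total: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Log conditional pmf of Y_a given Y_a + Y_b = total, over y = 0..total."""
    y = np.arange(total + 1)
    if phi == 0.0:
        logp = stats.binom.logpmf(y, total, n_a / (n_a + n_b))
    else:
        mu = total / (n_a + n_b)
        r_a, r_b = n_a / phi, n_b / phi
        p_a = r_a / (r_a + n_a * mu)
        p_b = r_b / (r_b + n_b * mu)
        logp = stats.nbinom.logpmf(y, r_a, p_a) + stats.nbinom.logpmf(
            total - y, r_b, p_b
        )
        logp -= logsumexp(logp)
    return logp


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lib_a: np.ndarray,
    lib_b: np.ndarray,
    phi: float,
    max_enumeration: int = 1_000_000,
    approximate: bool = False,
) -> float:
    """Two-sided sum-conditional NB exact p-value for one feature.

    ``lib_a``/``lib_b`` are effective library sizes (total mapped reads for
    expression; the reciprocal of the spike scaling factor for occupancy).
    Counts are rescaled to the common geometric-mean pseudo-library before
    summing, which makes the p-value invariant to uniform library rescaling.
    """
    counts_a = np.atleast_1d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_1d(np.asarray(counts_b, dtype=float))
    lib_a = np.atleast_1d(np.asarray(lib_a, dtype=float))
    lib_b = np.atleast_1d(np.asarray(lib_b, dtype=float))
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    M = _geometric_mean(np.concatenate([lib_a, lib_b]))
    y_a = int(np.round(np.sum(counts_a * (M / lib_a))))
    y_b = int(np.round(np.sum(counts_b * (M / lib_b))))
    total = y_a + y_b
    if total == 0:
        return 1.0
    n_a, n_b = len(counts_a), len(counts_b)
    if total > max_enumeration:
        if not approximate:
            raise ValueError(
                f"conditional total {total} exceeds the enumeration bound "
                f"{max_enumeration}; pass approximate=True for a normal "
                "approximation to the conditional law"
            )
        # normal approximation via the moments of the conditional law of Y_a
        frac = n_a / (n_a + n_b)
        mean = total * frac
        var = total * frac * (1 - frac) * (1.0 + phi * total / (n_a + n_b))
        z = (y_a - mean) / np.sqrt(var)
        return float(min(1.0, 2 * stats.norm.sf(abs(z))))
    logp = _conditional_log_pmf(total, n_a, n_b, phi)
    obs = logp[y_a]
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-10])))
    return min(1.0, p)


def median_of_ratios_lib_sizes(counts: np.ndarray) -> np.ndarray:
    """Effective library sizes by median-of-ratios to a pseudo-reference.

    The reference is the per-feature geometric mean across samples (features
    with any zero are skipped); each sample's size factor is the median of
    its count ratios to the reference.  Robust to composition bias when a
    substantial minority of features changes, which raw column totals are
    not; this is the normalisation family the standard count-based
    differential tools use.
    """
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature has positive counts in every sample")
    logref = np.log(counts[positive]).mean(axis=1)
    factors = np.exp(np.median(np.log(counts[positive]) - logref[:, None], axis=0))
    return factors / _geometric_mean(factors) * counts.sum(axis=0).mean()


def expression_lib_sizes(
    counts: np.ndarray, groups, mad_k: float = 2.5
) -> np.ndarray:
    """Composition-robust effective library sizes for grouped count data.

    Between-condition factors come from median-of-ratios on replicate-pooled
    counts (pooling shrinks the per-feature ratio noise), after excluding
    features whose log-ratio deviates from the group median by more than
    ``mad_k`` MADs in any condition -- a two-pass trim that removes genuinely
    shifted features from the normalisation set.  Within a condition the
    composition is identical across replicates, so per-replicate depth is
    taken from plain totals over the retained features.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    pooled = np.column_stack([counts[:, groups == g].sum(axis=1) for g in labels])
    positive = (pooled > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature has positive pooled counts in every group")
    logp = np.log(pooled[positive])
    logratio = logp - logp.mean(axis=1, keepdims=True)
    med = np.median(logratio, axis=0)
    dev = np.abs(logratio - med)
    mad = np.median(dev, axis=0)
    keep_rows = (dev <= mad_k * np.maximum(mad, 1e-8)).all(axis=1)
    if keep_rows.sum() < 10:
        keep_rows[:] = True  # degenerate trim; fall back to all features
    group_factor = {
        g: float(np.exp(np.median(logratio[keep_rows, j])))
        for j, g in enumerate(labels)
    }
    keep_idx = np.flatnonzero(positive)[keep_rows]
    depth = counts[keep_idx, :].sum(axis=0)
    out = np.empty(counts.shape[1])
    for g in labels:
        cols = groups == g
        rel = depth[cols] / depth[cols].mean()
        out[cols] = group_factor[g] * rel
    return out / _geometric_mean(out) * counts.sum(axis=0).mean()


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone enforced)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    if np.any((pvalues < 0) | (pvalues > 1) | ~np.isfinite(pvalues)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


def exact_test_table(
    counts: np.ndarray,
    feature_ids,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    lib_sizes: np.ndarray,
    phi: float | None = None,
    max_enumeration: int = 1_000_000,
    approximate: bool = True,
) -> pd.DataFrame:
    """Exact test per feature between two sample groups.

    Returns a frame with normalised group means, ``logFC`` (log2 of group b
    over group a, so "b relative to a"), raw ``pvalue`` and BH ``fdr``.
    When ``phi`` is None a common dispersion is estimated from the data.
    """
    counts = np.asarray(counts, dtype=float)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if phi is None:
        groups = np.where(mask_a, "a", np.where(mask_b, "b", "other"))
        use = mask_a | mask_b
        phi = estimate_common_dispersion(
            counts[:, use], lib_sizes[use], groups[use]
        ).phi
    M = _geometric_mean(lib_sizes[mask_a | mask_b])
    scaled = counts * (M / lib_sizes)[None, :]
    mean_a = scaled[:, mask_a].mean(axis=1)
    mean_b = scaled[:, mask_b].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logfc = np.log2(mean_b / mean_a)
    pvals = np.array(
        [
            nb_exact_test(
                counts[i, mask_a],
                counts[i, mask_b],
                lib_sizes[mask_a],
                lib_sizes[mask_b],
                phi,
                max_enumeration=max_enumeration,
                approximate=approximate,
            )
            for i in range(counts.shape[0])
        ]
    )
    return pd.DataFrame(
        {
            "feature": list(feature_ids),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "logFC": logfc,
            "pvalue": pvals,
            "fdr": bh_fdr(pvals),
            "phi": phi,
        }
    ).set_index("feature")


def independent_filter(
    mean_counts: np.ndarray,
    pvalues: np.ndarray,
    thresholds: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, np.ndarray, int]:
    """Independent filtering on the mean normalised count.

    Chooses the threshold (from a grid that should include 0) maximising the
    number of BH rejections at ``alpha`` among features at or above it, then
    re-runs BH on the surviving set.  Returns ``(threshold, fdr, n_reject)``
    where ``fdr`` is NaN for filtered-out features.  Deterministic: ties go
    to the smallest threshold.
    """
    mean_counts = np.asarray(mean_counts, dtype=float)
    pvalues = np.asarray(pvalues, dtype=float)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    if thresholds.size == 0:
        raise ValueError("threshold grid must be nonempty")
    best_t, best_r = thresholds[0], -1
    for t in thresholds:
        keep = mean_counts >= t
        r = int(np.sum(bh_fdr(pvalues[keep]) < alpha)) if keep.any() else 0
        if r > best_r:
            best_t, best_r = t, r
    keep = mean_counts >= best_t
    fdr = np.full(len(pvalues), np.nan)
    if keep.any():
        fdr[keep] = bh_fdr(pvalues[keep])
    return float(best_t), fdr, best_r


def classify_expression_changes(
    de_wt_vs_ko1: pd.DataFrame,
    de_wt_vs_ko2: pd.DataFrame,
    wt_rpkm: pd.Series,
    trajectory: dict[str, pd.DataFrame] | None = None,
    rpkm_min: float = 1.0,
    logfc_cut: float = 0.0,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-gene expression-change flags from the two knockout comparisons.

    ``de_wt_vs_ko*`` are :func:`exact_test_table` outputs (group a = WT, so
    negative logFC means loss in the knockout).  ``trajectory`` optionally
    maps {"d0_d3", "d0_d6", "d3_d6"} to WT-only comparisons (a = earlier
    timepoint) used for the ``increase_*`` flags.  Flags:

    * ``expressed``: WT RPKM >= ``rpkm_min``;
    * ``down_ko1/down_ko2/up_ko1/up_ko2``: FDR < ``fdr_cut`` and
      |logFC| >= ``logfc_cut`` in the corresponding direction;
    * ``severe_ko1/severe_ko2``: additionally |logFC| >= 1;
    * ``down_in_both``: expressed and down in both knockout lines;
    * ``increase_d0_d3`` etc.: significant WT increase over that interval.
    """
    if set(de_wt_vs_ko1.index) != set(de_wt_vs_ko2.index):
        raise ValueError("knockout comparisons cover different gene universes")
    genes = de_wt_vs_ko1.index
    de2 = de_wt_vs_ko2.loc[genes]
    wt_rpkm = wt_rpkm.reindex(genes)
    if wt_rpkm.isna().any():
        raise ValueError("wt_rpkm missing genes present in the test results")

    def sig(df, sign):
        directional = df["logFC"] * sign
        direction = directional >= logfc_cut if logfc_cut > 0 else directional > 0
        return (df["fdr"] < fdr_cut) & direction

    out = pd.DataFrame(index=genes)
    out["expressed"] = wt_rpkm >= rpkm_min
    out["down_ko1"] = sig(de_wt_vs_ko1, -1)
    out["down_ko2"] = sig(de2, -1)
    out["up_ko1"] = sig(de_wt_vs_ko1, +1)
    out["up_ko2"] = sig(de2, +1)
    out["severe_ko1"] = (de_wt_vs_ko1["fdr"] < fdr_cut) & (de_wt_vs_ko1["logFC"].abs() >= 1)
    out["severe_ko2"] = (de2["fdr"] < fdr_cut) & (de2["logFC"].abs() >= 1)
    out["down_in_both"] = out["expressed"] & out["down_ko1"] & out["down_ko2"]
    for key in ("d0_d3", "d0_d6", "d3_d6"):
        col = f"increase_{key}"
        if trajectory and key in trajectory:
            tr = trajectory[key]
            if set(tr.index) != set(genes):
                raise ValueError(f"trajectory {key} covers a different gene universe")
            tr = tr.loc[genes]
            out[col] = (tr["fdr"] < fdr_cut) & (tr["logFC"] > 0)
        else:
            out[col] = False
    out["osteogenic"] = out[["increase_d0_d3", "increase_d0_d6", "increase_d3_d6"]].any(axis=1)
    return out
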