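"""FPKM, normalisation and negative-binomial differential expression.

The DE recipe follows the classic count-based workflow: per-sample size
factors by the median-of-ratios rule, a negative-binomial noise model with
``Var = mu + alpha * mu^2``, a method-of-moments dispersion estimate shared
across transcripts, and a Wald test on the log2 fold change with a normal
reference distribution.  Significance is called at FDR < 0.01 (strict,
Benjamini-Hochberg) together with |log2FC| >= 2, i.e. at least a four-fold
change.

Dispersion is estimated per transcript from replicate variability and then
pooled across transcripts (cohort median): with two or three replicates per
group the per-transcript moment estimate is far too noisy to calibrate a
Wald statistic, while the pooled estimate is accurate whenever dispersions
are broadly shared, which is the regime this pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import CountMatrix, ExpressionMatrix, ValidationError

DISPERSION_FLOOR = 1e-8


@dataclass
class DEResult:
    transcript_id: str
    contrast: str
    baseMeanA: float
    baseMeanB: float
    log2FC: float
    pvalue: float
    fdr: float
    is_DE: bool = False


def compute_fpkm(counts: CountMatrix, lengths: dict[str, int]) -> ExpressionMatrix:
    """Fragments per kilobase of exon per million mapped fragments.

    ``FPKM_ij = count_ij * 1e9 / (length_i * N_j)`` where ``N_j`` is the
    total fragment count of sample j.
    """
    c = counts.counts
    missing = [t for t in c.index if t not in lengths]
    if missing:
        raise ValidationError(f"no length for transcripts: {missing[:5]}")
    lens = np.array([lengths[t] for t in c.index], dtype=float)
    if (lens <= 0).any():
        raise ValidationError("transcript lengths must be > 0")
    totals = c.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        zero = [s for s, n in zip(c.columns, totals) if n == 0]
        raise ValidationError(f"all-zero sample columns: {zero}")
    fpkm = c.to_numpy(dtype=float) * 1e9 / (lens[:, None] * totals[None, :])
    return ExpressionMatrix(
        fpkm=pd.DataFrame(fpkm, index=c.index, columns=c.columns),
        sample_sheet=counts.sample_sheet,
    )


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j, ``s_j`` is the median over transcripts (restricted to
    rows with a strictly positive geometric mean across samples) of
    ``count_ij / geomean_i``.
    """
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = c.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.log(arr).mean(axis=1)
    positive = np.isfinite(loggeo)
    if not positive.any():
        raise ValidationError(
            "no transcript has nonzero counts in every sample; supply a "
            "pseudo-reference or filter samples"
        )
    ratios = arr[positive] / np.exp(loggeo[positive])[:, None]
    s = np.median(ratios, axis=0)
    if (s <= 0).any():
        raise ValidationError("non-positive size factor")
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=c.columns)


def _mom_dispersion(q: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-transcript method-of-moments dispersion from within-group moments.

    ``alpha_i = (pooled within-group variance - mean) / mean^2``.  The pooled
    variance is divided by the median of ``chi2(df)/df`` before use: at the
    few degrees of freedom a 3-vs-3 design leaves, the sample variance is a
    strongly right-skewed estimate whose *median* sits well below the true
    variance, and the downstream pooling across transcripts is a median, so
    without this correction the shared dispersion would be biased low and
    the Wald test anti-conservative.
    """
    n_total = sum(g.size for g in groups)
    k = len(groups)
    df = max(n_total - k, 1)
    ss = np.zeros(q.shape[0])
    for g in groups:
        sub = q[:, g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss / df
    median_bias = stats.chi2.median(df) / df
    mu = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var / median_bias - mu) / mu**2
    alpha[~np.isfinite(alpha)] = -np.inf
    return alpha


def de_test(
    counts: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    contrast_name: str | None = None,
    epsilon: float = 1.0,
) -> list[DEResult]:
    """Negative-binomial Wald test of group B versus group A.

    Counts are normalised by median-of-ratios size factors computed on the
    contrast samples.  ``log2FC = log2((mean_B + eps) / (mean_A + eps))``
    with a pseudo-mean ``eps`` bounding fold changes when one group is all
    zero.  The Wald statistic divides log2FC by its delta-method standard
    error under ``Var = mu + alpha mu^2``; two-sided p-values come from the
    standard normal.  Transcripts with zero total count get p = 1.
    """
    if set(group_a) & set(group_b):
        raise ValidationError("contrast groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 replicates")
    for s in (*group_a, *group_b):
        if s not in counts.sample_ids:
            raise ValidationError(f"unknown sample {s!r}")
    name = contrast_name or "A_vs_B"

    sub = counts.counts[list(group_a) + list(group_b)]
    s = size_factors(sub)
    q = sub.to_numpy(dtype=float) / s.to_numpy()[None, :]
    na, nb = len(group_a), len(group_b)
    ga = np.arange(na)
    gb = np.arange(na, na + nb)

    mean_a = q[:, ga].mean(axis=1)
    mean_b = q[:, gb].mean(axis=1)
    log2fc = np.log2((mean_b + epsilon) / (mean_a + epsilon))

    alpha_i = _mom_dispersion(q, [ga, gb])
    # per-transcript moment estimates are hopeless at 2-3 replicates; share
    # the cohort median across transcripts
    informative = q.sum(axis=1) > 0
    finite = informative & np.isfinite(alpha_i)
    alpha_pool = float(np.median(alpha_i[finite])) if finite.any() else DISPERSION_FLOOR
    alpha = np.maximum(alpha_pool, DISPERSION_FLOOR) * np.ones_like(alpha_i)

    var_a = (mean_a + alpha * mean_a**2) / na
    var_b = (mean_b + alpha * mean_b**2) / nb
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_a / (mean_a + epsilon) ** 2 + var_b / (mean_b + epsilon) ** 2
    ) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    pvals = np.where(informative, np.minimum(pvals, 1.0), 1.0)
    log2fc = np.where(informative, log2fc, 0.0)

    fdr = bh_adjust(pvals)
    out = []
    for i, tid in enumerate(counts.counts.index):
        out.append(
            DEResult(
                transcript_id=tid,
                contrast=name,
                baseMeanA=float(mean_a[i]),
                baseMeanB=float(mean_b[i]),
                log2FC=float(log2fc[i]),
                pvalue=float(pvals[i]),
                fdr=float(fdr[i]),
            )
        )
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving).

    ``fdr_(i) = min_{j >= i} min(1, m * p_(j) / j)`` over the sorted vector.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be a 1-d vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def call_de(
    results: list[DEResult],
    fc_min_log2: float = 2.0,
    fdr_max: float = 0.01,
    fdr_inclusive: bool = False,
) -> tuple[list[DEResult], dict[str, dict[str, int]]]:
    """Set the DE flag (FDR < 0.01 and |log2FC| >= 2 by default) and count
    up/down-regulated transcripts per contrast."""
    summary: dict[str, dict[str, int]] = {}
    for r in results:
        fdr_ok = r.fdr <= fdr_max if fdr_inclusive else r.fdr < fdr_max
        r.is_DE = bool(fdr_ok and abs(r.log2FC) >= fc_min_log2)
        slot = summary.setdefault(r.contrast, {"up": 0, "down": 0, "total": 0})
        if r.is_DE:
            slot["total"] += 1
            slot["up" if r.log2FC > 0 else "down"] += 1
    return results, summary


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    cols = ["transcript_id", "contrast", "baseMeanA", "baseMeanB",
            "log2FC", "pvalue", "fdr", "is_DE"]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in results], columns=cols
    )
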