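"""Two-group differential expression and the signature-gating filter.

The negative-binomial Wald test here is a deliberately simple stand-in for a
full shrinkage-based RNA-seq test: median-of-ratios library normalization,
method-of-moments per-gene dispersion, and a Wald statistic on the log2 fold
change.  Pipelines that need an external test (DESeq2, edgeR, limma) supply
its per-gene table (gene, log2fc, p) instead; everything downstream only
consumes that table.

Significance gate: BH-adjusted p < 0.05 and |log2FC| > 0.75, both strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

DEFAULT_ALPHA = 0.05
DEFAULT_LFC_THRESHOLD = 0.75
_DISPERSION_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DegSummary:
    """Direction counts and median effect sizes of the significant genes."""

    n_up: int
    n_down: int
    median_lfc_up: float
    median_lfc_down: float


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors (genes x samples input).

    Only genes expressed in every sample contribute, as usual for the
    geometric-mean reference.
    """
    usable = np.all(counts > 0, axis=1)
    if not usable.any():
        return np.ones(counts.shape[1])
    log_counts = np.log(counts[usable].astype(float))
    ref = log_counts.mean(axis=1, keepdims=True)  # log geometric mean per gene
    return np.exp(np.median(log_counts - ref, axis=0))


def nb_wald_test(counts: pd.DataFrame, groups: pd.Series | np.ndarray) -> pd.DataFrame:
    """Per-gene NB Wald test of case vs control counts.

    Parameters
    ----------
    counts : DataFrame
        Integer counts, genes x samples.
    groups : array-like of {"case", "control"}
        One label per sample column.

    Returns
    -------
    DataFrame indexed by gene with columns ``log2fc`` and ``p``.

    Notes
    -----
    log2fc = log2((mean_case + 0.5) / (mean_ctrl + 0.5)) on normalized
    counts.  The Wald variance uses a method-of-moments dispersion pooled
    across groups, floored at 1e-8; the statistic is referred to a t
    distribution with n1+n2-2 df (small-sample correction for the
    estimated dispersion).  All-zero genes get p = 1, log2fc = 0.
    """
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValidationError(
                "counts must be integers; for non-count statistics supply an external per-gene table"
            )
        values = np.round(values).astype(np.int64)
    groups = np.asarray(groups)
    case = groups == "case"
    ctrl = groups == "control"
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValidationError("each group needs >= 2 samples")

    sf = size_factors(values)
    norm = values / sf
    mean_case = norm[:, case].mean(axis=1)
    mean_ctrl = norm[:, ctrl].mean(axis=1)
    log2fc = np.log2((mean_case + _PSEUDOCOUNT) / (mean_ctrl + _PSEUDOCOUNT))

    # method-of-moments NB dispersion phi: var = mu + phi mu^2, pooled
    def group_phi(block: np.ndarray) -> np.ndarray:
        mu = block.mean(axis=1)
        var = block.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (var - mu) / mu**2
        return np.where(np.isfinite(phi), phi, 0.0)

    phi = np.maximum((group_phi(norm[:, case]) + group_phi(norm[:, ctrl])) / 2.0, _DISPERSION_FLOOR)

    # Wald on log2 ratio; delta-method variance of log mean under NB
    n_case, n_ctrl = case.sum(), ctrl.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log_case = (1.0 / np.maximum(mean_case, _PSEUDOCOUNT) + phi) / n_case
        var_log_ctrl = (1.0 / np.maximum(mean_ctrl, _PSEUDOCOUNT) + phi) / n_ctrl
    se_log2 = np.sqrt(var_log_case + var_log_ctrl) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se_log2
    # t reference with n1+n2-2 df: small-sample correction for the
    # estimated dispersion entering the Wald variance
    p = 2.0 * stats.t.sf(np.abs(wald), df=n_case + n_ctrl - 2)

    all_zero = values.sum(axis=1) == 0
    log2fc[all_zero] = 0.0
    p[all_zero] = 1.0
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=counts.index)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def gene_stats_table(
    counts: pd.DataFrame | None = None,
    groups=None,
    external: pd.DataFrame | None = None,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Full per-gene statistics table (log2fc, p, padj, significant).

    Either raw ``counts`` + ``groups`` or an ``external`` table with columns
    (log2fc, p) indexed by gene may be supplied.
    """
    if external is not None:
        base = external[["log2fc", "p"]].copy()
    elif counts is not None:
        base = nb_wald_test(counts, groups)
    else:
        raise ValidationError("supply counts+groups or an external stats table")
    base["padj"] = bh_adjust(base["p"].to_numpy())
    base["significant"] = (base["padj"] < alpha) & (base["log2fc"].abs() > lfc_threshold)
    return base


def select_deg(
    stats_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> tuple[set[str], DegSummary]:
    """Significant genes: padj < alpha AND |log2fc| > lfc_threshold (strict).

    Returns the gene set plus up/down counts and per-direction median
    |log2fc| of the selected genes.
    """
    sig = stats_table[(stats_table["padj"] < alpha) & (stats_table["log2fc"].abs() > lfc_threshold)]
    up = sig[sig["log2fc"] > 0]
    down = sig[sig["log2fc"] < 0]
    summary = DegSummary(
        n_up=len(up),
        n_down=len(down),
        median_lfc_up=float(up["log2fc"].median()) if len(up) else float("nan"),
        median_lfc_down=float(down["log2fc"].median()) if len(down) else float("nan"),
    )
    return set(sig.index), summary
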