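"""Simplified negative-binomial differential expression and target nomination.

This module is deliberately a lightweight stand-in for a full DESeq2-style
analysis: median-of-ratios size factors, a moments-based common dispersion,
and a normal Wald test on the log2 fold change. Shrinkage, outlier
replacement and independent filtering are not reproduced. Genes passing
``|log2FC| > 0.5`` and ``p < 0.05`` are called differentially expressed,
and targets are nominated by intersecting each dataset's top genes ranked
by p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError
from .genomic_io import CountMatrix

__all__ = [
    "DEResult",
    "size_factors",
    "de_test",
    "nominate_targets",
]

DEFAULT_LFC_MIN = 0.5
DEFAULT_P_MAX = 0.05
DEFAULT_TOP_N = 10
PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 0.01


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential-expression call (knockdown vs control)."""

    gene: str
    baseMean: float
    log2fc: float
    pvalue: float
    padj: float
    direction: str  # "up" | "down" | "ns"


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean over samples, computed on
    genes with all-positive counts; each sample's factor is the median ratio
    of its counts to the reference.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_pos = np.all(counts > 0, axis=1)
    if not all_pos.any():
        raise UsageError(
            "no gene has positive counts in every sample; consider a "
            "pseudo-reference (counts + 1) fallback"
        )
    sub = counts[all_pos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.samples, name="size_factor")


def _dispersion(norm: np.ndarray, group_idx: list[np.ndarray]) -> float:
    """Common NB dispersion by method of moments, pooled across groups and genes.

    For each gene and group, alpha_hat = (var - mean) / mean^2 on normalized
    counts; estimates are pooled within gene across the two groups and then
    averaged across genes (per-gene values may be negative and are kept, so
    the average stays unbiased), floored at 0.01. Sharing one dispersion
    across genes is what keeps the normal Wald reference calibrated at the
    small group sizes (n = 2-3) this test targets.
    """
    per_gene = []
    for idx in group_idx:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / np.square(m)
        per_gene.append(a)
    pooled = np.nanmean(np.column_stack(per_gene), axis=1)
    pooled = pooled[np.isfinite(pooled)]
    if len(pooled) == 0:
        return DISPERSION_FLOOR
    return max(float(np.mean(pooled)), DISPERSION_FLOOR)


def de_test(
    cm: CountMatrix,
    lfc_min: float = DEFAULT_LFC_MIN,
    p_max: float = DEFAULT_P_MAX,
    reference: str | None = None,
) -> list[DEResult]:
    """Wald test of log2 fold change under an NB model, per gene.

    Requires exactly two condition groups with >= 2 samples each. The fold
    change is ``log2(m_treat / m_ref)`` on size-factor-normalized means with
    a 0.5 pseudo-count; its standard error comes from the delta method with
    NB variance ``m + alpha m^2``. Direction is "up"/"down" when
    ``|log2fc| > lfc_min`` and ``p < p_max``, else "ns". BH-adjusted
    p-values are reported alongside but the direction filter uses raw p.
    """
    groups = cm.groups()
    if len(groups) != 2:
        raise UsageError(f"need exactly 2 condition groups, got {sorted(groups)}")
    for name, members in groups.items():
        if len(members) < 2:
            raise UsageError(
                f"group {name!r} has {len(members)} sample(s); need >= 2 "
                "for a dispersion estimate"
            )
    names = sorted(groups)
    if reference is None:
        reference = names[0]
    elif reference not in groups:
        raise UsageError(f"reference group {reference!r} not in {names}")
    other = next(n for n in names if n != reference)

    sf = size_factors(cm).to_numpy()
    counts = cm.counts.to_numpy(dtype=float)
    norm = counts / sf[None, :]
    sample_pos = {s: i for i, s in enumerate(cm.samples)}
    idx_ref = np.array([sample_pos[s] for s in groups[reference]])
    idx_trt = np.array([sample_pos[s] for s in groups[other]])

    alpha = _dispersion(norm, [idx_ref, idx_trt])

    m_ref = norm[:, idx_ref].mean(axis=1)
    m_trt = norm[:, idx_trt].mean(axis=1)
    base_mean = norm.mean(axis=1)

    log2fc = np.log2(m_trt + PSEUDOCOUNT) - np.log2(m_ref + PSEUDOCOUNT)
    ln2_sq = np.log(2.0) ** 2

    def var_log2_mean(m: np.ndarray, n: int) -> np.ndarray:
        var_mean = (m + alpha * np.square(m)) / n
        return var_mean / (np.square(m + PSEUDOCOUNT) * ln2_sq)

    se = np.sqrt(
        var_log2_mean(m_ref, len(idx_ref)) + var_log2_mean(m_trt, len(idx_trt))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    padj = _bh_adjust(pvals)

    results = []
    for i, gene in enumerate(cm.genes):
        if abs(log2fc[i]) > lfc_min and pvals[i] < p_max:
            direction = "up" if log2fc[i] > 0 else "down"
        else:
            direction = "ns"
        results.append(
            DEResult(
                gene=gene,
                baseMean=float(base_mean[i]),
                log2fc=float(log2fc[i]),
                pvalue=float(pvals[i]),
                padj=float(padj[i]),
                direction=direction,
            )
        )
    return results


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def nominate_targets(
    results_by_dataset: dict[str, list[DEResult]],
    top_n: int | None = DEFAULT_TOP_N,
) -> pd.DataFrame:
    """Intersect each dataset's top significant genes, ranked by p-value.

    Per dataset, the ``top_n`` smallest p-values among significant genes
    (direction != ns) are taken; genes present in every dataset's top list
    are reported with per-dataset directions and a concordance flag.
    ``top_n=None`` intersects all significant genes. Datasets with fewer
    than ``top_n`` significant genes contribute all of them, with a warning.
    """
    if len(results_by_dataset) < 2:
        raise UsageError("need >= 2 datasets to intersect")
    tops: dict[str, dict[str, DEResult]] = {}
    for name in sorted(results_by_dataset):
        sig = [r for r in results_by_dataset[name] if r.direction != "ns"]
        sig.sort(key=lambda r: (r.pvalue, r.gene))
        if top_n is not None:
            if len(sig) < top_n:
                warnings.warn(
                    f"dataset {name!r} has only {len(sig)} significant genes "
                    f"(top_n={top_n}); using all",
                    stacklevel=2,
                )
            sig = sig[:top_n]
        tops[name] = {r.gene: r for r in sig}

    names = sorted(tops)
    shared = set.intersection(*(set(t) for t in tops.values()))
    rows = []
    for gene in sorted(shared):
        row: dict[str, object] = {"gene": gene}
        directions = []
        for name in names:
            r = tops[name][gene]
            row[f"log2fc_{name}"] = r.log2fc
            row[f"pvalue_{name}"] = r.pvalue
            row[f"direction_{name}"] = r.direction
            directions.append(r.direction)
        row["concordant"] = len(set(directions)) == 1
        row["min_pvalue"] = min(tops[n][gene].pvalue for n in names)
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["min_pvalue", "gene"]).reset_index(drop=True)
    return df
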