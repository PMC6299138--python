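"""Correlation analyses linking mutational and immune heterogeneity.

Pearson correlation is the workhorse: r with a two-sided t-test p-value
(t = r sqrt((n-2)/(1-r^2)) on n-2 df) and a Fisher-z 95% confidence
interval. The divergence of immune cell infiltration across a patient's loci
is 1 minus the average pairwise Pearson correlation of the 28-type score
vectors (0 = identical infiltration profiles, up to 2 for perfectly
anti-correlated ones). Group comparisons use the Mann-Whitney U test with an
exact null for small tie-free samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .panels import ANTI_TUMOR_CELLS, PRO_TUMOR_CELLS
from .types import ValidationError

EXACT_MWU_MAX_N = 25


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    ci_low: float
    ci_high: float


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson correlation with t-test p-value and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson needs two equal-length vectors")
    n = x.size
    if n < 3:
        raise ValidationError("pearson needs at least 3 pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum())
    if sx == 0 or sy == 0:
        raise ValidationError("pearson undefined for a constant vector")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    # Fisher z interval
    if abs(r) == 1.0:
        lo, hi = r, r
    else:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3) if n > 3 else np.inf
        lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    return CorrelationResult(r=r, p_value=p, n=n, ci_low=lo, ci_high=hi)


def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U statistic and p-value.

    Uses the exact null distribution when both groups have n <= 25 and the
    pooled data are tie-free, else the normal approximation with tie
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    exact = (
        len(a) <= EXACT_MWU_MAX_N
        and len(b) <= EXACT_MWU_MAX_N
        and len(np.unique(pooled)) == len(pooled)
    )
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def infiltration_divergence(cell_scores: pd.DataFrame) -> float:
    """1 - mean pairwise Pearson r between a patient's locus score vectors.

    ``cell_scores`` is cell types x loci for one patient (>= 2 loci, >= 3
    cell types with variation).
    """
    if cell_scores.shape[1] < 2:
        raise ValidationError("divergence needs at least two loci")
    if cell_scores.shape[0] < 3:
        raise ValidationError("divergence needs at least three cell types")
    rs = []
    for a, b in combinations(cell_scores.columns, 2):
        rs.append(pearson(cell_scores[a], cell_scores[b]).r)
    return float(1.0 - np.mean(rs))


def antitumor_protumor_correlation(cell_scores: pd.DataFrame) -> CorrelationResult:
    """Correlation between mean anti-tumor and mean pro-tumor infiltration.

    ``cell_scores`` is cell types x samples and must contain the 12
    anti-tumor populations (activated/memory T cells, Th1, Th17, ActDC,
    NK subsets, NKT) and the 8 pro-tumor ones (Treg, Th2, CD56dimNK, imDC,
    TAM, MDSC, Neutrophil, pDC).
    """
    names = set(cell_scores.index)
    missing = [c for c in (*ANTI_TUMOR_CELLS, *PRO_TUMOR_CELLS) if c not in names]
    if missing:
        raise ValidationError(f"missing cell-type score(s): {', '.join(missing)}")
    anti = cell_scores.loc[list(ANTI_TUMOR_CELLS)].mean(axis=0)
    pro = cell_scores.loc[list(PRO_TUMOR_CELLS)].mean(axis=0)
    return pearson(anti.to_numpy(), pro.to_numpy())


def het_vs_het(mutational: pd.Series, divergence: pd.Series) -> CorrelationResult:
    """Correlate per-patient mutational heterogeneity (ITH or CV) with the
    infiltration divergence across the same patients."""
    common = mutational.index.intersection(divergence.index)
    if len(common) < 3:
        raise ValidationError("need at least 3 patients with both statistics")
    return pearson(
        mutational.reindex(common).to_numpy(), divergence.reindex(common).to_numpy()
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values for a batch of tests (optional batch reports)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(q, 0.0, 1.0)
    return out
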