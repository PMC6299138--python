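"""ssGSEA enrichment scoring and assembly of the 278-feature immune matrix.

Single-sample GSEA ranks each sample's genes by expression and walks the
ranked list with a weighted running sum: in-set steps are weighted by
|rank|^alpha (alpha = 0.25 by default), out-of-set steps are uniform, and
the enrichment score is the integral (sum) of the running sum — the
single-sample convention, purely rank-based and therefore invariant under
monotone transforms of a sample's expression vector.

The immune map's input matrix has 278 features per sample in fixed block
order: neoantigen load (1), TCR clonality (1), expression of a 31-gene
immune-regulation panel as log2(TPM+1), 217 pathway enrichment scores and
28 immune-cell-type enrichment scores, both unity-normalized (per-feature
min-max to [0, 1] across samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import ExpressionMatrix, GeneSetCollection, ValidationError
from .panels import CYTOLYTIC_GENES, POPLAR_GENES

N_IMMUNE_GENES = 31
N_PATHWAYS = 217
N_CELL_TYPES = 28
N_FEATURES = 278
CYTOLYTIC_EPS = 0.01


@dataclass(frozen=True)
class SsgseaParams:
    alpha: float = 0.25
    normalization: str = "unity"  # unity | zscore | none

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError("ssGSEA alpha must be >= 0")
        if self.normalization not in ("unity", "zscore", "none"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")


def _rank_cache(expr: ExpressionMatrix, alpha: float):
    """Per-sample descending gene order and rank weights, computed once."""
    values = expr.df.to_numpy()
    n, m = values.shape
    orders = np.empty((m, n), dtype=np.intp)
    weights = np.empty((m, n))
    for j in range(m):
        x = values[:, j]
        ranks = rankdata(x)  # average ties, 1..n, n = highest expression
        order = np.argsort(-x, kind="stable")
        orders[j] = order
        weights[j] = np.abs(ranks[order]) ** alpha
    return orders, weights


def _set_scores(orders, weights, in_set: np.ndarray) -> np.ndarray:
    """Integrated running-sum ES for one set across all samples (vectorized)."""
    n = in_set.size
    n_out = n - in_set.sum()
    io = in_set[orders]  # samples x genes, in-set flags in ranked order
    w_in = np.where(io, weights, 0.0)
    cum_in = np.cumsum(w_in, axis=1) / w_in.sum(axis=1, keepdims=True)
    cum_out = np.cumsum(~io, axis=1) / n_out
    return (cum_in - cum_out).sum(axis=1)


def ssgsea_score(
    expr: ExpressionMatrix, gene_set: list[str], params: SsgseaParams = SsgseaParams()
) -> pd.Series:
    """Per-sample enrichment score of one gene set."""
    members = [g for g in set(gene_set) if g in expr.df.index]
    if not members:
        raise ValidationError(
            f"gene set has no overlap with the expression matrix: {gene_set[:5]}..."
        )
    in_set = np.asarray(expr.df.index.isin(members))
    if in_set.all():
        raise ValidationError("gene set covers the whole matrix; ES undefined")
    orders, weights = _rank_cache(expr, params.alpha)
    return pd.Series(_set_scores(orders, weights, in_set), index=expr.samples, name="ES")


def ssgsea_matrix(
    expr: ExpressionMatrix, collection: GeneSetCollection, params: SsgseaParams = SsgseaParams()
) -> pd.DataFrame:
    """Gene sets x samples enrichment-score matrix."""
    orders, weights = _rank_cache(expr, params.alpha)
    rows = {}
    for name in collection.names:
        members = [g for g in set(collection[name]) if g in expr.df.index]
        if not members:
            raise ValidationError(
                f"gene set {name!r} has no overlap with the expression matrix"
            )
        in_set = np.asarray(expr.df.index.isin(members))
        if in_set.all():
            raise ValidationError(f"gene set {name!r} covers the whole matrix; ES undefined")
        rows[name] = _set_scores(orders, weights, in_set)
    return pd.DataFrame(rows, index=expr.samples).T


def normalize_scores(raw: pd.DataFrame, mode: str = "unity") -> pd.DataFrame:
    """Per-feature normalization across samples (features are rows).

    ``unity`` min-max scales each feature to [0, 1] (a constant feature maps
    to 0.5); ``zscore`` centers and scales to unit population sd (a constant
    feature maps to 0).
    """
    if mode == "none":
        return raw.copy()
    if raw.shape[1] < 2:
        raise ValidationError("normalization needs at least two samples")
    vals = raw.to_numpy(dtype=float)
    if mode == "unity":
        lo = vals.min(axis=1, keepdims=True)
        hi = vals.max(axis=1, keepdims=True)
        span = hi - lo
        flat = span[:, 0] == 0
        span[flat] = 1.0
        out = (vals - lo) / span
        out[flat] = 0.5
    elif mode == "zscore":
        mean = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=0, keepdims=True)
        flat = sd[:, 0] == 0
        sd[flat] = 1.0
        out = (vals - mean) / sd
        out[flat] = 0.0
    else:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def cytolytic_activity(
    expr: ExpressionMatrix, sample: str | None = None, eps: float = CYTOLYTIC_EPS,
    form: str = "geometric",
) -> float | pd.Series:
    """Cytolytic activity from GZMA and PRF1 TPM.

    ``geometric`` (default) returns sqrt((GZMA+eps)(PRF1+eps)); ``product``
    returns the raw product, which induces the same sample ranking.
    """
    for g in CYTOLYTIC_GENES:
        if g not in expr.df.index:
            raise ValidationError(f"cytolytic activity needs gene {g!r} in the matrix")
    gzma = expr.df.loc["GZMA"] + eps
    prf1 = expr.df.loc["PRF1"] + eps
    if form == "geometric":
        act = np.sqrt(gzma * prf1)
    elif form == "product":
        act = gzma * prf1
    else:
        raise ValidationError(f"unknown cytolytic form {form!r}")
    act.name = "cytolytic_activity"
    if sample is None:
        return act
    if sample not in act.index:
        raise KeyError(f"unknown sample {sample!r}")
    return float(act[sample])


def poplar_panel(expr: ExpressionMatrix, sample: str | None = None) -> pd.DataFrame | pd.Series:
    """log2(TPM+1) of the 8 effector/IFN-gamma prognostic genes."""
    missing = [g for g in POPLAR_GENES if g not in expr.df.index]
    if missing:
        raise ValidationError(f"missing panel gene(s): {', '.join(missing)}")
    vals = np.log2(expr.df.loc[list(POPLAR_GENES)] + 1.0)
    if sample is None:
        return vals
    return vals[sample]


@dataclass
class FeatureMatrix:
    """Samples x 278 immune-map feature matrix with named column blocks."""

    df: pd.DataFrame
    blocks: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df.shape[1] != N_FEATURES:
            raise ValidationError(
                f"feature matrix must have {N_FEATURES} columns; found {self.df.shape[1]}"
            )
        if self.df.isna().to_numpy().any():
            raise ValidationError("feature matrix contains missing values")


def assemble_features(
    expr: ExpressionMatrix,
    neoantigen_loads: pd.Series,
    clonalities: pd.Series,
    immune_genes: list[str],
    pathways: GeneSetCollection,
    cell_types: GeneSetCollection,
    params: SsgseaParams = SsgseaParams(),
) -> FeatureMatrix:
    """Build the 278-feature matrix (2 + 31 + 217 + 28, fixed block order).

    ``neoantigen_loads`` and ``clonalities`` are per-sample series indexed by
    the expression matrix's sample ids; a sample missing from either is an
    error, as is any block-size mismatch.
    """
    if len(immune_genes) != N_IMMUNE_GENES:
        raise ValidationError(
            f"immune gene panel must have {N_IMMUNE_GENES} genes; found {len(immune_genes)}"
        )
    if len(pathways) != N_PATHWAYS:
        raise ValidationError(f"expected {N_PATHWAYS} pathway sets; found {len(pathways)}")
    if len(cell_types) != N_CELL_TYPES:
        raise ValidationError(f"expected {N_CELL_TYPES} cell-type sets; found {len(cell_types)}")
    samples = expr.samples
    for name, series in (("neoantigen_loads", neoantigen_loads), ("clonalities", clonalities)):
        orphans = [s for s in samples if s not in series.index]
        if orphans:
            raise ValidationError(f"{name} missing sample(s): {', '.join(orphans[:5])}")
    missing = [g for g in immune_genes if g not in expr.df.index]
    if missing:
        raise ValidationError(f"immune panel gene(s) absent from matrix: {', '.join(missing[:5])}")

    gene_block = np.log2(expr.df.loc[immune_genes] + 1.0).T
    gene_block.columns = [f"gene:{g}" for g in immune_genes]
    path_scores = normalize_scores(ssgsea_matrix(expr, pathways, params), "unity").T
    path_scores.columns = [f"pathway:{p}" for p in pathways.names]
    cell_scores = normalize_scores(ssgsea_matrix(expr, cell_types, params), "unity").T
    cell_scores.columns = [f"cell:{c}" for c in cell_types.names]

    df = pd.concat(
        [
            neoantigen_loads.reindex(samples).rename("neoantigen_load").astype(float),
            clonalities.reindex(samples).rename("tcr_clonality").astype(float),
            gene_block.reindex(samples),
            path_scores.reindex(samples),
            cell_scores.reindex(samples),
        ],
        axis=1,
    )
    blocks = {
        "neoantigen_load": ["neoantigen_load"],
        "tcr_clonality": ["tcr_clonality"],
        "immune_genes": list(gene_block.columns),
        "pathways": list(path_scores.columns),
        "cell_types": list(cell_scores.columns),
    }
    return FeatureMatrix(df, blocks)
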