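"""TCR repertoire summary statistics.

All metrics operate on productive clonotype counts (CDR3 amino-acid
sequences free of stop '*' and frameshift '_' markers) and use natural
logarithms:

* Shannon entropy H = -sum p_i ln p_i (nats);
* Simpson index sum p_i^2 (the dominance form — expansion of large clones
  increases it);
* clonality = 1 - H / ln(richness), with the monoclonal repertoire defined
  as clonality 1;
* dominant clones: frequency >= 0.5% by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import RepertoireTable, ValidationError

DOMINANT_THRESHOLD = 0.005


def productive(counts: pd.Series) -> pd.Series:
    """Drop non-productive clonotypes (CDR3 containing '*' or '_')."""
    idx = counts.index.astype(str)
    keep = ~(idx.str.contains(r"\*", regex=True) | idx.str.contains("_"))
    return counts[keep]


def _freqs(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValidationError("repertoire metrics need at least one clonotype")
    if (arr <= 0).any():
        raise ValidationError("clonotype counts must be positive")
    return arr / arr.sum()


def shannon_entropy(counts) -> float:
    """Shannon-Wiener diversity in nats."""
    p = _freqs(counts)
    return float(-(p * np.log(p)).sum())


def simpson_index(counts) -> float:
    """Simpson dominance sum p_i^2; 1 for a monoclonal repertoire."""
    p = _freqs(counts)
    return float((p ** 2).sum())


def clonality(counts) -> float:
    """1 - H/ln(richness); 1 when only a single clonotype is present."""
    p = _freqs(counts)
    if p.size == 1:
        return 1.0
    return float(1.0 - shannon_entropy(counts) / np.log(p.size))


def dominant_clones(
    counts: pd.Series, threshold: float = DOMINANT_THRESHOLD
) -> list[tuple[str, float]]:
    """Clonotypes at or above the frequency threshold, most expanded first."""
    p = _freqs(counts)
    freq = pd.Series(p, index=counts.index)
    hits = freq[freq >= threshold].sort_values(ascending=False, kind="stable")
    return list(hits.items())


@dataclass
class RepertoireSummary:
    sample_id: str
    richness: int
    shannon_entropy: float
    simpson_index: float
    clonality: float
    dominant_clones: list[tuple[str, float]]


def summarize(counts: pd.Series, sample_id: str, threshold: float = DOMINANT_THRESHOLD) -> RepertoireSummary:
    """All repertoire metrics for one sample's productive clonotypes."""
    prod = productive(counts)
    if prod.empty:
        raise ValidationError(f"sample {sample_id!r} has no productive clonotypes")
    return RepertoireSummary(
        sample_id=sample_id,
        richness=int(prod.size),
        shannon_entropy=shannon_entropy(prod),
        simpson_index=simpson_index(prod),
        clonality=clonality(prod),
        dominant_clones=dominant_clones(prod, threshold),
    )


def summarize_table(table: RepertoireTable, threshold: float = DOMINANT_THRESHOLD) -> pd.DataFrame:
    """Per-sample summary metrics as a tidy frame (one row per sample)."""
    rows = []
    for sid in table.samples:
        s = summarize(table.counts_for(sid), sid, threshold)
        rows.append(
            {
                "sample_id": s.sample_id,
                "richness": s.richness,
                "shannon_entropy": s.shannon_entropy,
                "simpson_index": s.simpson_index,
                "clonality": s.clonality,
                "n_dominant": len(s.dominant_clones),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def sharing_matrix(summaries: dict[str, RepertoireSummary]) -> pd.DataFrame:
    """Loci x loci counts of shared dominant clonotypes.

    Diagonal entries are each locus's own dominant-clone count; the matrix is
    symmetric by construction.
    """
    if len(summaries) < 2:
        raise ValidationError("sharing matrix needs at least two loci")
    ids = sorted(summaries)
    dom = {sid: {c for c, _ in summaries[sid].dominant_clones} for sid in ids}
    mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i in ids:
        for j in ids:
            mat.loc[i, j] = len(dom[i] & dom[j])
    return mat
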