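"""Somatic-variant filtering, burden, clonality and heterogeneity statistics.

The filter keeps high-confidence non-silent rare variants:

1. consequence in {missense, nonsense, frameshift, splice_site};
2. VAF > 0.05 or coverage >= 5x;
3. every population-database frequency < 0.005 (ExAC, ESP6500, dbSNP, 1000G;
   absence from a database counts as frequency 0).

Two clonality callers are provided. The normalized-MAF method scales each
VAF by 2/ploidy, divides by the locus maximum, and calls clonal at
nMAF >= 0.2. The regional method calls a mutation clonal iff it is present
in every sampled locus of the patient. Intratumoral heterogeneity (ITH) is
the subclonal fraction under the regional method; the coefficient of
variation (CV) of per-locus burden is the complementary statistic that
weighs total mutation counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import NONSILENT, MutationRecord, ValidationError

VAF_MIN = 0.05
COVERAGE_MIN = 5
POP_FREQ_MAX = 0.005
NMAF_CLONAL = 0.2


class ClonalityLabel(enum.Enum):
    CLONAL = "clonal"
    SUBCLONAL = "subclonal"


@dataclass(frozen=True)
class ClonalityCall:
    """One mutation's clonal/subclonal call under a named method."""

    mutation_key: tuple
    method: str  # "nmaf" or "regional"
    label: ClonalityLabel
    nmaf_value: float | None = None

    def __post_init__(self) -> None:
        if self.method == "nmaf" and self.nmaf_value is None:
            raise ValidationError("nmaf method requires an nmaf_value")


def filter_mutations(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Apply the three-step non-silent / confidence / rarity filter."""
    kept = []
    for r in records:
        if r.consequence not in NONSILENT:
            continue
        if not (r.vaf > VAF_MIN or r.coverage >= COVERAGE_MIN):
            continue
        if any(f >= POP_FREQ_MAX for f in r.pop_freqs.values()):
            continue
        kept.append(r)
    return kept


def tmb(records: Sequence[MutationRecord], patient_id: str, locus_id: str) -> int:
    """Total mutational burden: non-synonymous mutation count at one locus.

    ``records`` must already be filtered. Raises ``KeyError`` when the
    (patient, locus) pair never appears in the table at all.
    """
    loci_seen = {(r.patient_id, r.locus_id) for r in records}
    if (patient_id, locus_id) not in loci_seen:
        raise KeyError(f"unknown locus {patient_id}/{locus_id}")
    return sum(1 for r in records if r.patient_id == patient_id and r.locus_id == locus_id)


def tmb_table(records: Sequence[MutationRecord]) -> pd.Series:
    """Per-(patient, locus) mutation counts for a filtered table."""
    idx = pd.MultiIndex.from_tuples(
        sorted({(r.patient_id, r.locus_id) for r in records}),
        names=["patient_id", "locus_id"],
    )
    counts = pd.Series(0, index=idx, dtype=int)
    for r in records:
        counts.loc[(r.patient_id, r.locus_id)] += 1
    return counts


def classify_nmaf(
    records: Sequence[MutationRecord], ploidy_normalize: bool = True
) -> list[ClonalityCall]:
    """Normalized-MAF clonality for the mutations of one locus.

    Each VAF is ploidy-adjusted (x 2/ploidy, diploid reference) and divided
    by the locus maximum; nMAF >= 0.2 is clonal (boundary inclusive). Set
    ``ploidy_normalize=False`` to use raw VAFs.
    """
    if not records:
        raise ValidationError("classify_nmaf needs at least one record")
    loci = {(r.patient_id, r.locus_id) for r in records}
    if len(loci) > 1:
        raise ValidationError(f"classify_nmaf expects a single locus; got {sorted(loci)}")
    adj = np.array(
        [r.vaf * (2.0 / r.ploidy) if ploidy_normalize else r.vaf for r in records]
    )
    top = adj.max()
    if top <= 0:
        raise ValidationError("all adjusted MAFs are zero; nMAF undefined")
    calls = []
    for r, nmaf in zip(records, adj / top):
        label = ClonalityLabel.CLONAL if nmaf >= NMAF_CLONAL else ClonalityLabel.SUBCLONAL
        calls.append(ClonalityCall(r.key, "nmaf", label, nmaf_value=float(nmaf)))
    return calls


def presence_matrix(records: Sequence[MutationRecord], patient_id: str) -> pd.DataFrame:
    """Mutations x loci binary presence matrix for one patient.

    Rows are (gene, protein_change) keys, columns locus ids. Every locus in
    which the patient has at least one record contributes a column; the
    implicit all-zero germline row is not stored.
    """
    pat = [r for r in records if r.patient_id == patient_id]
    if not pat:
        raise ValidationError(f"no mutations for patient {patient_id!r}")
    loci = sorted({r.locus_id for r in pat})
    keys = sorted({(r.gene, r.protein_change) for r in pat})
    mat = pd.DataFrame(0, index=pd.MultiIndex.from_tuples(keys), columns=loci, dtype=int)
    for r in pat:
        mat.loc[(r.gene, r.protein_change), r.locus_id] = 1
    return mat


def classify_regional(presence: pd.DataFrame) -> list[ClonalityCall]:
    """Multi-region clonality: clonal iff present in every sampled locus."""
    if presence.shape[1] < 1:
        raise ValidationError("presence matrix needs at least one locus")
    calls = []
    all_present = presence.to_numpy().all(axis=1)
    for key, clonal in zip(presence.index, all_present):
        label = ClonalityLabel.CLONAL if clonal else ClonalityLabel.SUBCLONAL
        mkey = tuple(key) if isinstance(key, (tuple, list)) else (key,)
        calls.append(ClonalityCall(mkey, "regional", label))
    return calls


def ith(presence: pd.DataFrame) -> float:
    """Intratumoral heterogeneity: fraction of mutations not shared by all loci."""
    if presence.shape[0] == 0:
        raise ValidationError("ITH undefined for an empty presence matrix")
    calls = classify_regional(presence)
    subclonal = sum(1 for c in calls if c.label is ClonalityLabel.SUBCLONAL)
    return subclonal / len(calls)


def cv_tmb(tmbs: Sequence[float]) -> float:
    """Coefficient of variation of per-locus burden (n-1 sd / mean)."""
    arr = np.asarray(tmbs, dtype=float)
    if arr.size < 2:
        raise ValidationError("CV needs at least two loci")
    mean = arr.mean()
    if mean == 0:
        raise ValidationError("CV undefined when mean burden is zero")
    return float(arr.std(ddof=1) / mean)
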