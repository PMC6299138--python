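"""Core in-memory containers shared by all pipeline stages.

The pipeline operates on four kinds of tables: per-locus somatic mutation
records, a genes x samples TPM expression matrix, per-sample CDR3 clonotype
count tables, and named gene-set collections. Each container validates its
invariants at construction so downstream code can assume well-formed data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input value violates a domain invariant."""


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


class Consequence(enum.Enum):
    """Functional consequence of a coding somatic variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    SILENT = "silent"
    OTHER = "other"

    @classmethod
    def parse(cls, text: str) -> "Consequence":
        """Map a consequence string to the enum; unknown strings become OTHER."""
        try:
            return cls(text.strip().lower())
        except ValueError:
            return cls.OTHER


#: consequences retained by the non-silent filter
NONSILENT = frozenset(
    {Consequence.MISSENSE, Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.SPLICE_SITE}
)


@dataclass(frozen=True)
class MutationRecord:
    """A single somatic variant observed in one tumor locus.

    ``vaf`` is the variant allele fraction, ``coverage`` the read depth at the
    site, ``pop_freqs`` the population allele frequencies reported by germline
    databases (a missing database entry means the variant was absent there and
    is treated as frequency 0), and ``ploidy`` the locus-level tumor ploidy
    used for allele-frequency normalization.
    """

    patient_id: str
    locus_id: str
    gene: str
    protein_change: str
    consequence: Consequence
    vaf: float
    coverage: int
    pop_freqs: Mapping[str, float] = field(default_factory=dict)
    ploidy: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(
                f"vaf must lie in [0, 1]; got {self.vaf} for "
                f"{self.patient_id}/{self.locus_id} {self.gene} {self.protein_change}"
            )
        if self.coverage < 0:
            raise ValidationError(f"coverage must be non-negative; got {self.coverage}")
        for db, freq in self.pop_freqs.items():
            if not 0.0 <= freq <= 1.0:
                raise ValidationError(f"population frequency {db}={freq} outside [0, 1]")
        if self.ploidy <= 0:
            raise ValidationError(f"ploidy must be positive; got {self.ploidy}")

    @property
    def key(self) -> tuple[str, str, str]:
        """Mutation identity within a patient: (gene, protein_change, patient)."""
        return (self.patient_id, self.gene, self.protein_change)


class ExpressionMatrix:
    """Genes x samples TPM matrix with unique gene symbols and sample ids.

    Samples are identified by ``"<patient>_<locus>"`` strings throughout the
    pipeline. Values are non-negative TPM; no library-size renormalization is
    performed here.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("expression matrix contains missing values")
        if (values < 0).any():
            rows, cols = np.nonzero(values < 0)
            cells = [
                f"({df.index[r]}, {df.columns[c]})={values[r, c]}"
                for r, c in zip(rows[:5], cols[:5])
            ]
            raise ValidationError(f"negative TPM entries: {', '.join(cells)}")
        self.df = df.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def sample_vector(self, sample: str) -> pd.Series:
        if sample not in self.df.columns:
            raise KeyError(f"unknown sample {sample!r}")
        return self.df[sample]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({len(self.genes)} genes x {len(self.samples)} samples)"


_AA = set("ACDEFGHIKLMNPQRSTVWY")


class RepertoireTable:
    """CDR3 clonotype read counts for a set of samples.

    Stored long-form with columns ``sample_id``, ``junction_aa`` and
    ``duplicate_count``. Clonotype identity is the CDR3 amino-acid sequence;
    V/J gene calls are not part of identity. Sequences containing ``*`` (stop)
    or ``_`` (frameshift marker) are retained on input and excluded later by
    the productive filter in the repertoire metrics.
    """

    COLUMNS = ("sample_id", "junction_aa", "duplicate_count")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"repertoire table missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["duplicate_count"] = df["duplicate_count"].astype(int)
        if (df["duplicate_count"] < 1).any():
            raise ValidationError("clonotype counts must be >= 1")
        if (df["junction_aa"].str.len() == 0).any():
            raise ValidationError("empty CDR3 sequence")
        if df.duplicated(subset=["sample_id", "junction_aa"]).any():
            dup = df[df.duplicated(subset=["sample_id", "junction_aa"])].iloc[0]
            raise ValidationError(
                f"duplicate clonotype {dup.junction_aa!r} in sample {dup.sample_id!r}"
            )
        self.df = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def counts_for(self, sample_id: str) -> pd.Series:
        """Clonotype counts for one sample, indexed by CDR3 amino-acid string."""
        sub = self.df[self.df["sample_id"] == sample_id]
        if sub.empty:
            raise KeyError(f"no clonotypes for sample {sample_id!r}")
        return sub.set_index("junction_aa")["duplicate_count"]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RepertoireTable):
            return False
        a = self.df.sort_values(["sample_id", "junction_aa"]).reset_index(drop=True)
        b = other.df.sort_values(["sample_id", "junction_aa"]).reset_index(drop=True)
        return a.equals(b)


class GeneSetCollection:
    """An ordered mapping from gene-set name to its member gene list."""

    def __init__(self, sets: Mapping[str, Iterable[str]]):
        clean: dict[str, list[str]] = {}
        for name, genes in sets.items():
            genes = [g.strip() for g in genes]
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if name in clean:
                raise ValidationError(f"duplicate gene-set name {name!r}")
            clean[name] = genes
        self.sets = clean

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self.sets)} sets)"


def sample_id(patient_id: str, locus_id: str) -> str:
    """Canonical flat sample identifier for a (patient, locus) pair."""
    return f"{patient_id}_{locus_id}"
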