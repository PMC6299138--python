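"""Mutant-peptide enumeration and neoantigen affinity filtering.

Binding-affinity prediction is upstream (netMHCpan-style, nM units); this
module enumerates the 8-11-mer windows around a missense residue and applies
the published affinity filters to mutant/wild-type pairs:

* ``strict``  — mutant < 50 nM and mutant < 0.7 x wild-type (differential
  agretopicity), used for correlation analyses;
* ``presence`` — mutant < 500 nM, used for presence/absence heat maps.

Neoantigen load is counted at mutation level: a mutation contributes 1 when
at least one of its peptide/allele pairs survives the filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .types import ValidationError

STRICT_NM = 50.0
STRICT_RATIO = 0.7
PRESENCE_NM = 500.0
MIN_LEN, MAX_LEN = 8, 11


@dataclass(frozen=True)
class PeptideCandidate:
    """One mutant peptide window; ``offset`` is the 1-based position of the
    mutated residue within the window."""

    length: int
    offset: int
    sequence: str

    def __post_init__(self) -> None:
        if not (MIN_LEN <= self.length <= MAX_LEN):
            raise ValidationError(f"peptide length {self.length} outside [{MIN_LEN},{MAX_LEN}]")
        if not (1 <= self.offset <= self.length):
            raise ValidationError(f"offset {self.offset} outside peptide")
        if len(self.sequence) != self.length:
            raise ValidationError("sequence length mismatch")


def enumerate_peptides(protein: str, mut_pos: int, mut_aa: str) -> list[PeptideCandidate]:
    """All 8-11-mer windows covering a mutated residue.

    ``mut_pos`` is 1-based within ``protein``; windows are clipped at the
    protein termini and duplicates removed. An interior position far from
    both termini yields 8+9+10+11 = 38 candidates.
    """
    n = len(protein)
    if not (1 <= mut_pos <= n):
        raise ValidationError(f"mutation position {mut_pos} outside protein of length {n}")
    mutated = protein[: mut_pos - 1] + mut_aa + protein[mut_pos:]
    out: list[PeptideCandidate] = []
    seen: set[tuple[int, int, str]] = set()
    for length in range(MIN_LEN, MAX_LEN + 1):
        for start in range(max(0, mut_pos - length), min(mut_pos - 1, n - length) + 1):
            seq = mutated[start: start + length]
            offset = mut_pos - start
            key = (length, offset, seq)
            if key in seen:
                continue
            seen.add(key)
            out.append(PeptideCandidate(length, offset, seq))
    return out


def filter_neoantigens(pairs: pd.DataFrame, mode: str = "strict") -> pd.DataFrame:
    """Keep affinity rows passing the chosen filter.

    ``pairs`` is an affinity table with ``mutant_nM`` and ``wildtype_nM``
    columns. All thresholds are strict inequalities.
    """
    if mode == "strict":
        keep = (pairs["mutant_nM"] < STRICT_NM) & (
            pairs["mutant_nM"] < STRICT_RATIO * pairs["wildtype_nM"]
        )
    elif mode == "presence":
        keep = pairs["mutant_nM"] < PRESENCE_NM
    else:
        raise ValueError(f"unknown filter mode {mode!r} (expected 'strict' or 'presence')")
    return pairs[keep].reset_index(drop=True)


def neoantigen_load(filtered: pd.DataFrame, patient_id: str, locus_id: str) -> int:
    """Distinct source mutations with a surviving pair at one locus."""
    sub = filtered[
        (filtered["patient_id"] == patient_id) & (filtered["locus_id"] == locus_id)
    ]
    return int(sub.drop_duplicates(subset=["gene", "protein_change"]).shape[0])


def neoantigen_load_table(filtered: pd.DataFrame) -> pd.Series:
    """Per-(patient, locus) distinct-mutation neoantigen counts."""
    if filtered.empty:
        return pd.Series(dtype=int)
    dedup = filtered.drop_duplicates(subset=["patient_id", "locus_id", "gene", "protein_change"])
    return dedup.groupby(["patient_id", "locus_id"]).size().astype(int)
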