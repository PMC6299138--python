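"""Filtering, burden, clonality and heterogeneity statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from immunemap.types import Consequence, MutationRecord, ValidationError
from immunemap.variants import (
    ClonalityLabel,
    classify_nmaf,
    classify_regional,
    cv_tmb,
    filter_mutations,
    ith,
    presence_matrix,
    tmb,
)


def rec(**kw):
    base = dict(
        patient_id="P01", locus_id="L1", gene="KRAS", protein_change="p.G12D",
        consequence=Consequence.MISSENSE, vaf=0.3, coverage=100,
        pop_freqs={}, ploidy=2.0,
    )
    base.update(kw)
    return MutationRecord(**base)


class TestFilter:
    def test_silent_dropped(self):
        assert filter_mutations([rec(consequence=Consequence.SILENT, vaf=0.5)]) == []

    def test_low_vaf_rescued_by_coverage(self):
        # VAF below 0.05 but coverage exactly at the 5x boundary is kept
        r = rec(vaf=0.04, coverage=5)
        assert filter_mutations([r]) == [r]

    def test_low_vaf_and_low_coverage_dropped(self):
        assert filter_mutations([rec(vaf=0.04, coverage=4)]) == []

    def test_common_variant_dropped(self):
        r = rec(pop_freqs={"dbSNP": 0.01})
        assert filter_mutations([r]) == []

    def test_rare_in_all_databases_kept(self):
        r = rec(pop_freqs={"ExAC": 0.004, "ESP6500": 0.0, "dbSNP": 0.0049, "1000G": 0.0})
        assert filter_mutations([r]) == [r]


class TestTmb:
    def test_counts_per_locus(self):
        recs = [rec(gene=f"G{i}", protein_change=f"p.A{i}V") for i in range(3)]
        assert tmb(recs, "P01", "L1") == 3

    def test_unknown_locus_raises(self):
        with pytest.raises(KeyError, match="unknown locus"):
            tmb([rec()], "P01", "L9")

    def test_empty_table_raises(self):
        with pytest.raises(KeyError):
            tmb([], "P01", "L1")


class TestNmaf:
    def test_hand_computed_diploid(self):
        recs = [
            rec(gene=f"G{i}", protein_change=f"p.A{i}V", vaf=v)
            for i, v in enumerate([0.4, 0.1, 0.05])
        ]
        calls = classify_nmaf(recs)
        assert [round(c.nmaf_value, 6) for c in calls] == [1.0, 0.25, 0.125]
        assert [c.label for c in calls] == [
            ClonalityLabel.CLONAL, ClonalityLabel.CLONAL, ClonalityLabel.SUBCLONAL,
        ]

    def test_boundary_inclusive(self):
        recs = [
            rec(gene="A", protein_change="p.A1V", vaf=0.5),
            rec(gene="B", protein_change="p.B1V", vaf=0.1),  # nMAF exactly 0.2
        ]
        calls = classify_nmaf(recs)
        assert calls[1].nmaf_value == pytest.approx(0.2)
        assert calls[1].label is ClonalityLabel.CLONAL

    def test_ploidy_normalization(self):
        # triploid locus: VAF scaled by 2/3 before normalization
        recs = [
            rec(gene="A", protein_change="p.A1V", vaf=0.3, ploidy=3.0),
            rec(gene="B", protein_change="p.B1V", vaf=0.3, ploidy=3.0),
        ]
        calls = classify_nmaf(recs)
        assert all(c.nmaf_value == pytest.approx(1.0) for c in calls)
        raw = classify_nmaf(recs, ploidy_normalize=False)
        assert all(c.nmaf_value == pytest.approx(1.0) for c in raw)

    def test_all_zero_vaf_raises(self):
        with pytest.raises(ValidationError, match="nMAF undefined"):
            classify_nmaf([rec(vaf=0.0)])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=20))
    def test_max_is_always_clonal(self, vafs):
        recs = [rec(gene=f"G{i}", protein_change=f"p.A{i}V", vaf=v) for i, v in enumerate(vafs)]
        calls = classify_nmaf(recs)
        top = max(calls, key=lambda c: c.nmaf_value)
        assert top.nmaf_value == pytest.approx(1.0)
        assert top.label is ClonalityLabel.CLONAL
        # idempotence: same input, same output
        assert classify_nmaf(recs) == calls


class TestRegionalAndIth:
    def _presence(self, rows, loci):
        return pd.DataFrame(
            rows, index=[(f"G{i}", f"p.A{i}V") for i in range(len(rows))], columns=loci
        )

    def test_single_locus_all_clonal(self):
        pres = self._presence([[1], [1]], ["L1"])
        assert all(c.label is ClonalityLabel.CLONAL for c in classify_regional(pres))
        assert ith(pres) == 0.0

    def test_partial_presence_subclonal(self):
        pres = self._presence([[1, 1, 0]], ["L1", "L2", "L3"])
        assert classify_regional(pres)[0].label is ClonalityLabel.SUBCLONAL

    def test_ith_fraction(self):
        rows = [[1, 1, 1]] * 4 + [[1, 0, 0]] * 6
        assert ith(self._presence(rows, ["L1", "L2", "L3"])) == pytest.approx(0.6)

    def test_ith_zero_iff_all_shared(self):
        rows = [[1, 1], [1, 1]]
        assert ith(self._presence(rows, ["L1", "L2"])) == 0.0

    def test_empty_matrix_raises(self):
        with pytest.raises(ValidationError):
            ith(self._presence([], ["L1"]))

    def test_presence_matrix_from_records(self):
        recs = [
            rec(locus_id="L1"), rec(locus_id="L2"),
            rec(gene="TP53", protein_change="p.R175H", locus_id="L1"),
        ]
        pres = presence_matrix(recs, "P01")
        assert pres.shape == (2, 2)
        assert pres.loc[("KRAS", "p.G12D")].tolist() == [1, 1]
        assert pres.loc[("TP53", "p.R175H")].tolist() == [1, 0]


class TestCv:
    def test_equal_tmbs_zero(self):
        assert cv_tmb([7, 7, 7]) == 0.0

    def test_hand_value(self):
        assert cv_tmb([10, 30]) == pytest.approx(0.7071067811865476)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.integers(1, 500), min_size=2, max_size=8),
        st.floats(0.1, 50.0),
    )
    def test_scale_invariance(self, tmbs, k):
        assert cv_tmb([k * t for t in tmbs]) == pytest.approx(cv_tmb(tmbs), rel=1e-9)

    def test_zero_mean_raises(self):
        with pytest.raises(ValidationError):
            cv_tmb([0, 0])

    def test_single_locus_raises(self):
        with pytest.raises(ValidationError):
            cv_tmb([5])
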