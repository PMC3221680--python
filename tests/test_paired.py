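import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methdrift.config import ThresholdConfig
from methdrift.paired import (PairDriftClassifier, classify_pair,
                              classify_pairs, mutation_concordance,
                              summarize_pairs)


class TestClassifyPair:
    def test_two_fold_increase_above_cutoff(self):
        call = classify_pair(13.4, 27.4)
        assert call.drift == "increase"
        assert call.concordance == "discordant"
        assert call.fold == pytest.approx(27.4 / 13.4)

    def test_fold_below_two_is_no_drift(self):
        call = classify_pair(10, 19)
        assert call.drift == "none"
        assert call.concordance == "discordant"

    def test_zero_primary_means_infinite_fold(self):
        call = classify_pair(0, 20)
        assert call.fold == math.inf
        assert call.drift == "increase"

    def test_fold_without_density_clause_is_no_drift(self):
        call = classify_pair(8, 3)
        assert call.fold == pytest.approx(8 / 3)
        assert call.drift == "none"
        assert call.concordance == "concordant_unmethylated"

    def test_both_zero_is_no_change(self):
        call = classify_pair(0, 0)
        assert call.fold == 1.0
        assert call.drift == "none"
        assert call.concordance == "concordant_unmethylated"

    def test_exact_two_fold_is_strict(self):
        assert classify_pair(20, 40).drift == "none"
        assert classify_pair(20, 40.0001).drift == "increase"

    def test_missing_input_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_pair(float("nan"), 10)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0, max_value=100, allow_nan=False),
           st.floats(min_value=0, max_value=100, allow_nan=False))
    def test_swap_symmetry(self, p, m):
        """Swapping primary and metastasis swaps increase and decrease and
        preserves fold and concordance."""
        a, b = classify_pair(p, m), classify_pair(m, p)
        assert a.fold == b.fold
        assert a.concordance == b.concordance
        swap = {"increase": "decrease", "decrease": "increase", "none": "none"}
        assert swap[a.drift] == b.drift

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=100, allow_nan=False),
           st.floats(min_value=0.1, max_value=100, allow_nan=False),
           st.floats(min_value=0.1, max_value=3.0))
    def test_fold_is_scale_invariant(self, p, m, c):
        cfg = ThresholdConfig()
        a = classify_pair(p, m, cfg)
        b = classify_pair(min(c * p, 100), min(c * m, 100), cfg)
        if c * p <= 100 and c * m <= 100:
            assert b.fold == pytest.approx(a.fold, rel=1e-9)

    def test_every_pair_gets_exactly_one_label_each(self):
        for p in (0, 10, 20, 50):
            for m in (0, 10, 20, 50):
                call = classify_pair(p, m)
                assert call.concordance in ("concordant_methylated",
                                            "concordant_unmethylated",
                                            "discordant")
                assert call.drift in ("increase", "decrease", "none")


class TestPairDriftClassifier:
    def test_predict_matches_scalar_rule(self):
        X = np.array([[13.4, 27.4], [10, 19], [0, 20], [8, 3]])
        clf = PairDriftClassifier()
        assert clf.predict(X).tolist() == ["increase", "none", "increase",
                                           "none"]
        assert clf.get_params() == {"density_cutoff": 15.0, "fold_cutoff": 2.0}


def _calls(cm, cu, d, inc, dec, none):
    """Synthesize a classified-call frame with the given composition."""
    rows = []
    comps = ([("concordant_methylated",)] * cm
             + [("concordant_unmethylated",)] * cu
             + [("discordant",)] * d)
    drifts = ["increase"] * inc + ["decrease"] * dec + ["none"] * none
    for i, ((conc,), drift) in enumerate(zip(comps, drifts)):
        rows.append({"patient_id": f"p{i % 16}", "locus_id": f"L{i % 13}",
                     "primary_density": 0.0, "metastasis_density": 0.0,
                     "concordance": conc, "drift": drift, "fold": 1.0})
    return pd.DataFrame(rows)


class TestSummarizePairs:
    def test_printed_cohort_percentages(self):
        """205 pairs split 47/136/22 with 11 increases and 14 decreases."""
        calls = _calls(cm=47, cu=136, d=22, inc=11, dec=14, none=180)
        s = summarize_pairs(calls)
        assert s.n_pairs_total == 205
        assert s.n_concordant == 183
        assert s.percentages["concordant"] == "89%"
        assert s.percentages["concordant_methylated"] == "23%"
        assert s.percentages["discordant"] == "11%"
        assert s.percentages["increase"] == "5%"
        assert s.percentages["decrease"] == "7%"

    def test_concordance_counts_partition_total(self):
        calls = _calls(cm=3, cu=4, d=5, inc=2, dec=1, none=9)
        s = summarize_pairs(calls)
        assert (s.n_concordant_methylated + s.n_concordant_unmethylated
                + s.n_discordant == s.n_pairs_total)

    def test_all_concordant_unmethylated(self):
        calls = _calls(cm=0, cu=10, d=0, inc=0, dec=0, none=10)
        s = summarize_pairs(calls)
        assert s.percentages["discordant"] == "0%"
        assert s.n_increase == 0

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_pairs(_calls(0, 0, 0, 0, 0, 0))


class TestMutationConcordance:
    @staticmethod
    def _pairs(n):
        return pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "primary_sample": [f"p{i}_P" for i in range(n)],
            "metastasis_sample": [f"p{i}_M" for i in range(n)],
            "interval_months": [3.0] * n,
            "timing": ["synchronous"] * n,
        })

    def test_kras_discordance_formats_18_percent(self):
        """11 KRAS-involved pairs of which 2 are mutant in the primary only."""
        rows = []
        for i in range(16):
            for suffix in ("P", "M"):
                if i < 9:
                    status = "mutant"
                elif i < 11:
                    status = "mutant" if suffix == "P" else "wildtype"
                else:
                    status = "wildtype"
                rows.append({"sample_id": f"p{i}_{suffix}", "gene": "KRAS",
                             "status": status})
        res = mutation_concordance(pd.DataFrame(rows), self._pairs(16))
        row = res.set_index("gene").loc["KRAS"]
        assert row["n_pairs_with_mutation"] == 11
        assert row["n_discordant"] == 2
        assert row["discordance_pct"] == "18%"

    def test_no_mutant_pairs_rate_is_missing(self):
        mut = pd.DataFrame({"sample_id": ["p0_P", "p0_M"],
                            "gene": ["p53", "p53"],
                            "status": ["wildtype", "wildtype"]})
        res = mutation_concordance(mut, self._pairs(1))
        assert res.loc[0, "discordance_pct"] is None

    def test_mutant_in_both_is_concordant(self):
        mut = pd.DataFrame({"sample_id": ["p0_P", "p0_M"],
                            "gene": ["KRAS", "KRAS"],
                            "status": ["mutant", "mutant"]})
        res = mutation_concordance(mut, self._pairs(1))
        assert res.loc[0, "discordance_pct"] == "0%"

    def test_missing_status_excluded_and_counted(self):
        mut = pd.DataFrame({"sample_id": ["p0_P", "p1_P", "p1_M"],
                            "gene": ["KRAS"] * 3,
                            "status": ["mutant", "mutant", "mutant"]})
        res = mutation_concordance(mut, self._pairs(2))
        assert res.loc[0, "n_excluded_missing"] == 1
        assert res.loc[0, "n_pairs_with_mutation"] == 1
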