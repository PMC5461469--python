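"""Hazard prevalence, guideline agreement, the NOAEL screening rule,
28d->90d predictivity and the factor-3 DNEL check."""

import numpy as np
import pandas as pd
import pytest

from oratox.concordance import (
    ContingencyTable,
    bulgheroni_table,
    factor3_check,
    guideline_agreement,
    hazard_prevalence,
    noael_pairs,
    oral_nontoxic_percent,
    pair_noael_ld50,
    taylor_filter,
    taylor_predictivity,
)
from oratox.dossier import StudyRecord, SubstanceRecord


def study(sid, value, *, endpoint="acute_oral", guideline="TG401",
          klimisch=1, key=True, ra=False):
    return StudyRecord(sid, endpoint, guideline, klimisch, key, ra, value)


def paired_studies(cells):
    """One substance per pair-count: (noael28, ld50) repeated n times."""
    studies = []
    i = 0
    for (noael, ld50), n in cells:
        for _ in range(n):
            sid = f"S{i:05d}"
            studies.append(study(sid, noael, endpoint="repeated_28d",
                                 guideline="TG407"))
            studies.append(study(sid, ld50))
            i += 1
    return studies


class TestHazardPrevalence:
    def _substances(self, pos, neg, code="H302"):
        subs = []
        for i in range(pos + neg):
            subs.append(SubstanceRecord(
                f"S{i}", hazard_flags={code: "positive" if i < pos else "negative"}
            ))
        return subs

    def test_percent_arithmetic(self):
        # 1072 / (1072 + 4677) = 18.65% -> 18.6 at one decimal
        prev = hazard_prevalence(self._substances(1072, 4677))
        assert prev.loc["H302", "conclusive_positive_pct"] == 18.6

    def test_zero_positive(self):
        prev = hazard_prevalence(self._substances(0, 50))
        assert prev.loc["H302", "conclusive_positive_pct"] == 0.0

    def test_no_conclusive_records_undefined(self):
        subs = [SubstanceRecord("S1", hazard_flags={"H300": "data_lacking"})]
        prev = hazard_prevalence(subs)
        assert np.isnan(prev.loc["H300", "conclusive_positive_pct"])

    def test_nontoxic_complement_uses_rounded_percents(self):
        flags = pd.DataFrame({
            "H300": ["positive"] * 33 + ["negative"] * 5709,
            "H301": ["positive"] * 225 + ["negative"] * 5517,
            "H302": ["positive"] * 1072 + ["negative"] * 4670,
            "H303": ["positive"] * 23 + ["negative"] * 5719,
        })
        prev = hazard_prevalence(flags)
        assert oral_nontoxic_percent(prev) == pytest.approx(
            100.0 - prev["conclusive_positive_pct"].sum()
        )


class TestGuidelineAgreement:
    def test_both_below_threshold_agree(self):
        studies = [study("S1", 1500.0, guideline="TG401"),
                   study("S1", 1800.0, guideline="TG423")]
        mat = guideline_agreement(studies)
        assert mat[("pct", "TG423")]["TG401"] == 100.0
        assert mat[("n", "TG423")]["TG401"] == 1

    def test_opposite_classes_disagree(self):
        studies = [study("S1", 1500.0, guideline="TG401"),
                   study("S1", 2500.0, guideline="TG420")]
        mat = guideline_agreement(studies)
        assert mat[("pct", "TG420")]["TG401"] == 0.0

    def test_self_consistency_on_diagonal(self):
        studies = [study("S1", 2200.0, guideline="TG425"),
                   study("S1", 2800.0, guideline="TG425"),
                   study("S2", 1500.0, guideline="TG425"),
                   study("S2", 2500.0, guideline="TG425")]
        mat = guideline_agreement(studies)
        assert mat[("pct", "TG425")]["TG425"] == 50.0
        assert mat[("n", "TG425")]["TG425"] == 2

    def test_matrix_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        studies = []
        for i in range(120):
            for g in rng.choice(["TG401", "TG420", "TG423"], 2, replace=False):
                studies.append(study(f"S{i}", float(rng.uniform(100, 5000)),
                                     guideline=g))
        mat = guideline_agreement(studies)
        pct = mat["pct"]
        assert np.allclose(pct.to_numpy(float), pct.to_numpy(float).T,
                           equal_nan=True)
        vals = pct.to_numpy(float)
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 100


# Printed-table cell counts: (noael28 band, ld50 band) -> count
GREY_CELLS = [((100.0, 1000.0), 660), ((100.0, 3000.0), 1301),
              ((500.0, 1000.0), 183), ((500.0, 3000.0), 3126)]
WHITE_CELLS = [((100.0, 1000.0), 237), ((100.0, 3000.0), 411),
               ((500.0, 1000.0), 49), ((500.0, 3000.0), 928)]


class TestBulgheroni:
    def test_grey_cells_npv_ppv(self):
        res = bulgheroni_table(paired_studies(GREY_CELLS), scope="all")
        assert res.table.tp == 660
        assert res.table.fp == 1301
        assert res.table.fn == 183
        assert res.table.tn == 3126
        assert res.npv_pct == 94.5
        assert res.ppv_pct == 33.7

    def test_white_cells_avoidable_count(self):
        res = bulgheroni_table(paired_studies(WHITE_CELLS), scope="key_only")
        assert res.avoidable_count == 928
        assert res.n_substances == 1625

    def test_all_positive_correct_has_undefined_npv(self):
        table = ContingencyTable(tp=10, fp=0, fn=0, tn=0)
        assert table.ppv == 100.0
        assert table.npv is None

    def test_cell_totals_conserved(self):
        studies = paired_studies(GREY_CELLS)
        res = bulgheroni_table(studies, scope="all")
        assert res.table.total == res.n_substances == 5270

    def test_matches_brute_force_recount(self):
        from oratox.synthetic import (GeneratorConfig, generate_fingerprints,
                                      generate_repeated_dose_studies)

        cfg = GeneratorConfig(seed=21, n_substances=400, n_modules=4)
        subs = generate_fingerprints(cfg)
        rep = generate_repeated_dose_studies(subs, cfg)
        res = bulgheroni_table(rep, scope="all")
        pairs = pair_noael_ld50(rep, "all")
        tn = int(((pairs["noael28"] > 200) & (pairs["ld50"] >= 2000)).sum())
        fn = int(((pairs["noael28"] > 200) & (pairs["ld50"] < 2000)).sum())
        assert res.table.tn == tn
        assert res.npv_pct == round(100.0 * tn / (tn + fn), 1)

    def test_empty_intersection_is_error(self):
        with pytest.raises(ValueError, match="no substances"):
            bulgheroni_table([study("S1", 500.0)])


class TestTaylor:
    def _substances(self):
        return [
            SubstanceRecord("S1", hazard_flags={"H301": "negative",
                                                "H302": "negative"}),
            SubstanceRecord("S2", hazard_flags={"H301": "positive"}),
            SubstanceRecord("S3", hazard_flags={"H302": "negative"}),
        ]

    def _studies(self):
        return [
            study("S1", 1200.0, endpoint="repeated_28d", guideline="TG407",
                  klimisch=1),
            study("S2", 1500.0, endpoint="repeated_28d", guideline="TG407",
                  klimisch=1),
            study("S3", 800.0, endpoint="repeated_28d", guideline="TG407",
                  klimisch=3),
        ]

    def test_constraint_flags(self):
        flags = taylor_filter(self._substances(), self._studies())
        assert flags.loc["S1", "passes"]          # reliable, no positives
        assert not flags.loc["S2", "passes"]      # H301 positive
        assert not flags.loc["S3", "passes"]      # Klimisch 3 only
        assert flags.loc["S1", "high_dose_high_noael"]
        assert not flags.loc["S3", "high_dose_high_noael"]

    def test_predictivity_all_equal_pairs(self):
        pairs = pd.DataFrame({"noael28": [1000.0, 1500.0],
                              "noael90": [1000.0, 1500.0]})
        out = taylor_predictivity(pairs)
        assert out == {"n_high28": 2, "pct_high90_given_high28": 100.0}

    def test_pair_below_threshold_excluded(self):
        pairs = pd.DataFrame({"noael28": [999.0], "noael90": [1500.0]})
        out = taylor_predictivity(pairs)
        assert out["n_high28"] == 0
        assert out["pct_high90_given_high28"] is None

    def test_tuned_conditional_concordance(self):
        from oratox.synthetic import (GeneratorConfig, generate_fingerprints,
                                      generate_repeated_dose_studies)

        cfg = GeneratorConfig(seed=8, n_substances=2000, n_modules=4,
                              p_high90_given_high28=0.70)
        subs = generate_fingerprints(cfg)
        pairs = noael_pairs(generate_repeated_dose_studies(subs, cfg))
        out = taylor_predictivity(pairs)
        assert out["pct_high90_given_high28"] == pytest.approx(70.0, abs=3.0)


class TestFactor3:
    def test_printed_counts_arithmetic(self):
        pairs = pd.DataFrame({
            "noael28": [300.0] * 133,
            "noael90": [50.0] * 11 + [200.0] * 122,
        })
        out = factor3_check(pairs)
        assert out["n_below_one_third"] == 11
        assert out["pct_within"] == 91.7

    def test_exact_one_third_counts_as_within(self):
        out = factor3_check(pd.DataFrame({"noael28": [300.0],
                                          "noael90": [100.0]}))
        assert out["n_below_one_third"] == 0

    def test_clearly_below(self):
        out = factor3_check(pd.DataFrame({"noael28": [300.0],
                                          "noael90": [50.0]}))
        assert out["n_below_one_third"] == 1

    def test_zero_pairs_is_error(self):
        with pytest.raises(ValueError):
            factor3_check(pd.DataFrame({"noael28": [], "noael90": []}))
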