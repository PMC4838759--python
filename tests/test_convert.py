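"""Matrix-to-matrix conversion: coefficients, fallback policy, pivoting,
uncertainty propagation, and round-trip identities."""

import numpy as np
import pandas as pd
import pytest

import popblood as pb
from popblood.datatypes import PolicyError, TargetLookupError
from popblood.qc import clean_pipeline


class TestSingleConversion:
    def test_compound_specific_coefficient(self):
        out = pb.convert(100.0, "beta-HCH", "whole_blood", "plasma")
        assert out.converted_concentration == pytest.approx(182.0)
        assert out.source == "bundled_table"
        assert out.relative_se == pytest.approx(0.02 / 1.82)

    def test_identity(self):
        out = pb.convert(50.0, "beta-HCH", "plasma", "plasma")
        assert out.converted_concentration == 50.0
        assert out.relative_se == 0.0
        assert out.source == "identity"

    def test_unknown_pcb_uses_class_average(self):
        out = pb.convert(100.0, "PCB-999", "whole_blood", "plasma",
                         chemicals=_with_unknown("PCB-999", "pcb"))
        assert out.converted_concentration == pytest.approx(168.58, abs=0.5)
        assert out.source == "class_average"

    def test_pesticide_class_average_needs_force(self):
        chems = _with_unknown("mirex", "pesticide_chc")
        with pytest.raises(PolicyError):
            pb.convert(100.0, "mirex", "whole_blood", "plasma", chemicals=chems)
        out = pb.convert(100.0, "mirex", "whole_blood", "plasma",
                         chemicals=chems, force_class_average=True)
        assert out.source == "class_average"

    def test_unknown_chemical_without_class(self):
        with pytest.raises(TargetLookupError):
            pb.convert(100.0, "mystery", "whole_blood", "plasma")

    def test_linearity(self):
        one = pb.convert(1.0, "PBDE-47", "whole_blood", "plasma")
        many = pb.convert(37.5, "PBDE-47", "whole_blood", "plasma")
        assert many.converted_concentration == pytest.approx(
            37.5 * one.converted_concentration
        )

    def test_round_trip_identity(self):
        forward = pb.convert(123.4, "beta-HCH", "plasma", "dbs", prefer_fitted=True)
        back = pb.convert(forward.converted_concentration, "beta-HCH",
                          "dbs", "plasma", prefer_fitted=True)
        assert back.converted_concentration == pytest.approx(123.4, rel=1e-10)

    def test_unity_default_for_agreeing_dbs(self):
        """Whole-blood/DBS coefficients consistent with one default to
        exactly 1 unless the fitted value is preferred."""
        unity = pb.convert(100.0, "trans-nonachlor", "dbs", "whole_blood")
        assert unity.source == "unity_dbs"
        assert unity.converted_concentration == 100.0
        fitted = pb.convert(100.0, "trans-nonachlor", "dbs", "whole_blood",
                            prefer_fitted=True)
        assert fitted.converted_concentration == pytest.approx(100.0 * 1.00)
        # PCB-118 (1.18, se 0.06) genuinely differs from one: no unity default
        diff = pb.convert(100.0, "PCB-118", "dbs", "whole_blood")
        assert diff.converted_concentration == pytest.approx(118.0)

    def test_pivot_relative_se_is_rss(self, coefficients):
        """A chemical with no direct plasma~dbs entry pivots through whole
        blood with root-sum-square relative SE."""
        table = coefficients[~((coefficients.chemical == "beta-HCH")
                               & (coefficients.y_matrix == "plasma")
                               & (coefficients.x_matrix == "dbs"))]
        out = pb.convert(100.0, "beta-HCH", "dbs", "plasma",
                         coefficients=table, prefer_fitted=True)
        assert out.source.endswith("pivot")
        assert out.converted_concentration == pytest.approx(100 * 1.82 * 1.03)
        expected = np.hypot(0.02 / 1.82, 0.01 / 1.03)
        assert out.relative_se == pytest.approx(expected)

    def test_direct_and_pivot_paths_agree(self, coefficients):
        """For every chemical with both paths, the direct plasma~dbs
        coefficient matches the pivoted product within combined SEs."""
        pd_fits = coefficients[(coefficients.y_matrix == "plasma")
                               & (coefficients.x_matrix == "dbs")]
        for _, row in pd_fits.iterrows():
            direct = pb.lookup_coefficient(row.chemical, "plasma", "dbs")
            pw = pb.lookup_coefficient(row.chemical, "plasma", "whole_blood")
            wd = pb.lookup_coefficient(row.chemical, "whole_blood", "dbs")
            pivot = pw.beta * wd.beta
            combined_se = direct.beta * np.hypot(
                pw.se / pw.beta, wd.se / wd.beta
            ) + direct.se
            assert abs(direct.beta - pivot) <= 3 * combined_se + 0.05


class TestBatchConversion:
    def test_noise_free_inversion(self, noise_free_cohort):
        """Converting noise-free DBS values to plasma with the fitted
        coefficients reproduces the generated plasma values."""
        spec, panel, _, chem_table, truth = noise_free_cohort
        cleaned, _ = clean_pipeline(panel, chem_table, screen=False)
        fits = pb.fit_all_pairs(cleaned)
        # restrict to fully detected chemicals: half-IDL substitutes
        # legitimately distort both the fits and the latent comparison
        censored = set(cleaned[cleaned.below_idl].chemical)
        dbs = cleaned[(cleaned.matrix == "dbs") & ~cleaned.chemical.isin(censored)]
        out = pb.batch_convert(dbs, "plasma", coefficients=fits, prefer_fitted=True)
        merged = out[out.converted].merge(truth, on=["participant_id", "chemical"])
        good = merged[merged.conversion_source == "fitted"]
        assert len(good) > 100
        assert np.allclose(good.concentration_ng_per_L, good.plasma_latent, rtol=1e-9)

    def test_round_trip_batch(self, stochastic_cohort):
        _, panel, _, chem_table, _ = stochastic_cohort
        cleaned, _ = clean_pipeline(panel, chem_table, screen=False)
        plasma = cleaned[cleaned.matrix == "plasma"]
        to_dbs = pb.batch_convert(plasma, "dbs", prefer_fitted=True)
        back = pb.batch_convert(to_dbs[to_dbs.converted], "plasma", prefer_fitted=True)
        merged = back.merge(plasma, on=["participant_id", "chemical"],
                            suffixes=("_rt", "_orig"))
        merged = merged[merged.converted_rt if "converted_rt" in merged else merged.converted]
        assert np.allclose(merged.concentration_ng_per_L_rt,
                           merged.concentration_ng_per_L_orig, rtol=1e-10)

    def test_unconvertible_rows_flagged(self):
        panel = pd.DataFrame(
            {
                "participant_id": ["P01"],
                "chemical": ["PCB-110"],  # no DBS coefficient exists
                "matrix": ["dbs"],
                "replicate": [1],
                "concentration_ng_per_L": [10.0],
                "below_idl": [False],
            }
        )
        out = pb.batch_convert(panel, "plasma")
        assert not out.converted.iloc[0]
        assert out.conversion_source.iloc[0] == "unconvertible"
        assert out.concentration_ng_per_L.iloc[0] == 10.0
        assert out.matrix.iloc[0] == "dbs"

    def test_median_consistency_with_cohort_summaries(self):
        """Converting the bundled whole-blood median of beta-HCH to plasma
        with its coefficient lands within 3% of the bundled plasma median
        (667.7 * 1.82 = 1215 vs 1242.5) — a consistency check on the
        bundled tables, not an equality."""
        from popblood.registry import builtin_wb_medians

        wb_median = builtin_wb_medians()["beta-HCH"]
        out = pb.convert(wb_median, "beta-HCH", "whole_blood", "plasma")
        assert out.converted_concentration == pytest.approx(1242.5, rel=0.03)


def _with_unknown(name: str, chem_class: str) -> pd.DataFrame:
    chems = pb.builtin_chemicals()
    row = {c: np.nan for c in chems.columns}
    row.update(chemical=name, chem_class=chem_class)
    return pd.concat([chems, pd.DataFrame([row])], ignore_index=True)
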