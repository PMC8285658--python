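"""Ratio computation, Cauchy fitting, CDF inversion and tail selection."""

import math

import numpy as np
import pytest

from orfwalk.ratio_stats import (
    CauchyFit,
    RatioRecord,
    build_histogram,
    cauchy_cdf,
    cauchy_f,
    fit_cauchy,
    invert_cdf,
    load_table1,
    ratios_from_log_table,
    reproduce_table1_analysis,
    select_tails,
)


class TestRatiosFromLogTable:
    def test_study_rows(self, table1):
        ratios = {r.transcript_id: r for r in ratios_from_log_table(table1)}
        assert ratios["SCH_0029"].rounded == pytest.approx(1.799)
        assert ratios["SCH_0044"].rounded == pytest.approx(0.069)
        assert ratios["SCH_0229"].ratio == pytest.approx(1.0)  # reference row

    def test_equal_logs_give_unity(self):
        import pandas as pd

        df = pd.DataFrame({"transcript_id": ["t"], "log10_control": [-1.5],
                           "log10_noise": [-1.5]})
        (record,) = ratios_from_log_table(df)
        assert record.ratio == pytest.approx(1.0)

    def test_non_finite_log_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"transcript_id": ["bad"], "log10_control": [math.nan],
                           "log10_noise": [0.0]})
        with pytest.raises(ValueError, match="bad"):
            ratios_from_log_table(df)


class TestHistogram:
    def test_half_open_binning(self):
        hist = build_histogram([0.1, 0.3, 0.31], bin_width=0.2)
        assert hist.counts == (1, 2)

    def test_empty_input(self):
        assert build_histogram([], bin_width=0.2).counts == ()

    def test_value_on_edge_goes_right(self):
        hist = build_histogram([0.2], bin_width=0.2)
        assert hist.counts == (0, 1)

    def test_counts_conserved_on_study_table(self, table1):
        ratios = ratios_from_log_table(table1)
        hist = build_histogram(ratios, bin_width=0.2)
        assert hist.total == 500
        # the modal bin contains the unity ratio
        modal = int(np.argmax(hist.counts))
        lo, hi = hist.edges[modal], hist.edges[modal + 1]
        assert lo <= 1.0 < hi

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            build_histogram([1.0], bin_width=0.0)


class TestCauchyCurve:
    fit = CauchyFit(A=100.0, x0=1.0, gamma=0.3, sse=0.0)

    def test_peak_value(self):
        assert cauchy_f(1.0, self.fit) == pytest.approx(100.0)

    def test_half_width_at_half_maximum(self):
        assert cauchy_f(1.3, self.fit) == pytest.approx(50.0)
        assert cauchy_f(0.7, self.fit) == pytest.approx(50.0)

    def test_symmetry(self):
        for d in (0.1, 0.5, 2.0):
            assert cauchy_f(1.0 + d, self.fit) == pytest.approx(
                cauchy_f(1.0 - d, self.fit))

    def test_cdf_median_and_quartile(self):
        assert cauchy_cdf(1.0, self.fit) == pytest.approx(0.5)
        assert cauchy_cdf(1.3, self.fit) == pytest.approx(0.75)

    def test_cdf_symmetry(self):
        for d in (0.2, 1.0, 5.0):
            assert cauchy_cdf(1.0 + d, self.fit) + cauchy_cdf(1.0 - d, self.fit) \
                == pytest.approx(1.0)


class TestFitCauchy:
    def test_exact_curve_recovered_to_machine_precision(self):
        true = CauchyFit(A=100.0, x0=1.0, gamma=0.3, sse=0.0)
        centers = np.arange(0.1, 3.0, 0.2)
        counts = cauchy_f(centers, true)
        from orfwalk.ratio_stats import HistogramSpec

        hist = HistogramSpec(bin_width=0.2, origin=0.0,
                             counts=tuple(counts))
        fit = fit_cauchy(hist)
        assert fit.A == pytest.approx(100.0, rel=1e-6)
        assert fit.x0 == pytest.approx(1.0, abs=1e-6)
        assert fit.gamma == pytest.approx(0.3, rel=1e-6)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_perturbed_counts_keep_location_within_half_bin(self, rng):
        true = CauchyFit(A=80.0, x0=1.4, gamma=0.25, sse=0.0)
        centers = np.arange(0.1, 3.0, 0.2)
        counts = cauchy_f(centers, true) + rng.choice([-1.0, 1.0], len(centers))
        from orfwalk.ratio_stats import HistogramSpec

        hist = HistogramSpec(bin_width=0.2, origin=0.0,
                             counts=tuple(np.maximum(counts, 0.0)))
        fit = fit_cauchy(hist)
        assert abs(fit.x0 - 1.4) < 0.1

    def test_degenerate_histogram_rejected(self):
        from orfwalk.ratio_stats import HistogramSpec

        hist = HistogramSpec(bin_width=0.2, origin=0.0, counts=(0, 5, 3, 0))
        with pytest.raises(ValueError):
            fit_cauchy(hist)


class TestInvertCdf:
    fit = CauchyFit(A=50.0, x0=1.007, gamma=0.087, sse=0.0)

    def test_median(self):
        assert invert_cdf(0.5, self.fit) == pytest.approx(1.007, abs=1e-9)

    def test_upper_quartile(self):
        assert invert_cdf(0.75, self.fit) == pytest.approx(1.007 + 0.087, abs=1e-9)

    @pytest.mark.parametrize("p", [0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99])
    def test_agrees_with_closed_form(self, p):
        closed = self.fit.x0 + self.fit.gamma * math.tan(math.pi * (p - 0.5))
        assert invert_cdf(p, self.fit) == pytest.approx(closed, abs=1e-9)

    @pytest.mark.parametrize("p", [0.01, 0.2, 0.5, 0.8, 0.99])
    def test_round_trip_through_cdf(self, p):
        assert cauchy_cdf(invert_cdf(p, self.fit), self.fit) == \
            pytest.approx(p, abs=1e-9)

    def test_out_of_range_rejected(self):
        for p in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                invert_cdf(p, self.fit)


class TestSelectTails:
    def test_all_at_location_empty(self):
        fit = CauchyFit(A=10.0, x0=1.0, gamma=0.1, sse=0.0)
        ratios = [RatioRecord(f"t{i}", 1.0) for i in range(10)]
        sel = select_tails(ratios, fit)
        assert sel.decreased == () and sel.increased == ()

    def test_planted_outliers_and_only_them(self, rng):
        null = []
        while len(null) < 480:
            x = 1.0 + 0.087 * math.tan(math.pi * (rng.random() - 0.5))
            if 0.7 <= x <= 1.3:
                null.append(x)
        ratios = [RatioRecord(f"null_{i}", x) for i, x in enumerate(null)]
        ratios += [RatioRecord(f"up_{i}", 5.0) for i in range(10)]
        ratios += [RatioRecord(f"down_{i}", 0.05) for i in range(10)]
        # bin width below the expected half width, so the peak is resolved
        fit = fit_cauchy(build_histogram(ratios, 0.1))
        sel = select_tails(ratios, fit)
        assert set(sel.increased_ids) == {f"up_{i}" for i in range(10)}
        assert set(sel.decreased_ids) == {f"down_{i}" for i in range(10)}

    def test_value_exactly_on_cutoff_excluded(self):
        fit = CauchyFit(A=10.0, x0=1.0, gamma=0.1, sse=0.0)
        cutoff = invert_cdf(0.95, fit)
        ratios = [RatioRecord("edge", cutoff), RatioRecord("beyond", cutoff + 0.01)]
        sel = select_tails(ratios, fit)
        assert sel.increased_ids == ["beyond"]
        assert [r.transcript_id for r in sel.on_cutoff] == ["edge"]

    def test_order_invariance_and_extremity_order(self, rng):
        values = [0.1, 0.2, 3.5, 4.0, 1.0, 1.01]
        fit = CauchyFit(A=10.0, x0=1.0, gamma=0.05, sse=0.0)
        ratios = [RatioRecord(f"t{i}", v) for i, v in enumerate(values)]
        sel1 = select_tails(ratios, fit)
        sel2 = select_tails(list(reversed(ratios)), fit)
        assert sel1 == sel2
        assert [r.ratio for r in sel1.decreased] == [0.1, 0.2]
        assert [r.ratio for r in sel1.increased] == [4.0, 3.5]


class TestStudyAnalysis:
    def test_fixture_shape(self, table1):
        assert len(table1) == 500
        ref = table1[table1.transcript_id == "SCH_0229"]
        assert ref.log10_control.iloc[0] == 0.0 and ref.log10_noise.iloc[0] == 0.0

    def test_reproduction_selects_published_tails(self):
        result = reproduce_table1_analysis()
        sel = result["selection"]
        assert len(sel.increased) == 8
        assert len(sel.decreased) == 18
        # borderline endocuticle glycoprotein SgAbd-4 sits just below the cutoff
        ratios = {r.transcript_id: r.ratio for r in result["ratios"]}
        assert sel.upper_cutoff - 0.05 < ratios["SCH_0144"] < sel.upper_cutoff
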