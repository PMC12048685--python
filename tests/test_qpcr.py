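"""Ct algebra: relative levels, enrichment, standard curves, polysome profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iresact import qpcr, synth
from iresact.qpcr import (
    absolute_quantify,
    fit_standard_curve,
    no_rt_delta,
    polysome_distribution,
    rel_quantity,
    reporter_activity,
    rnaser_enrichment,
)

cts = st.floats(min_value=5, max_value=40, allow_nan=False)


class TestRelQuantity:
    @pytest.mark.parametrize(
        "ct, ref, expected",
        [(20, 20, 1.0), (21, 20, 0.5), (18, 20, 4.0)],
    )
    def test_closed_form(self, ct, ref, expected):
        assert rel_quantity(ct, ref) == pytest.approx(expected)

    def test_missing_ct_propagates(self):
        assert math.isnan(rel_quantity(float("nan"), 20))
        assert math.isnan(rel_quantity(20, float("nan")))

    @given(cts, cts)
    @settings(deadline=None)
    def test_reciprocal_identity(self, a, b):
        assert rel_quantity(a, b) * rel_quantity(b, a) == pytest.approx(1.0)

    @given(cts, cts, st.floats(min_value=0.01, max_value=5))
    @settings(deadline=None)
    def test_strictly_decreasing_in_ct(self, ct, ref, delta):
        assert rel_quantity(ct + delta, ref) < rel_quantity(ct, ref)


class TestStandardCurve:
    def test_noiseless_efficiency_two_series(self):
        pairs = [(q, 20 - math.log2(q)) for q in (1, 0.1, 0.01, 1e-3, 1e-4)]
        curve = fit_standard_curve(pairs)
        assert curve.slope == pytest.approx(-1 / math.log10(2), abs=1e-9)
        assert curve.slope == pytest.approx(-3.3219, abs=1e-4)
        assert curve.efficiency == pytest.approx(2.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.warning == ""

    def test_printed_dilution_range_has_five_points(self):
        # tenfold steps from 1 pg down to 0.1 fg = 1e-4 pg
        assert len(synth.DILUTION_SERIES_PG) == 5
        assert synth.DILUTION_SERIES_PG[0] == 1.0
        assert synth.DILUTION_SERIES_PG[-1] == pytest.approx(1e-4)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_standard_curve([(1, 20), (0.1, 23.3)])

    def test_zero_quantity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_standard_curve([(0, 20), (0.1, 23.3), (0.01, 26.6)])

    def test_off_efficiency_warns(self):
        pairs = [(q, 20 - math.log(q) / math.log(1.7)) for q in (1, 0.1, 0.01)]
        assert "efficiency" in fit_standard_curve(pairs).warning

    def test_noiseless_round_trip_exact(self):
        truth, design = synth.qpcr_preset("dilution", seed=0)
        table, _ = synth.make_ct_table(truth, design)
        pairs = [
            (float(a.split("@")[1]), ct) for a, ct in zip(table.amplicon, table.ct)
        ]
        curve = fit_standard_curve(pairs)
        for q_true, ct in pairs:
            q_hat, extrapolated = absolute_quantify(ct, curve)
            assert abs(q_hat - q_true) / q_true < 1e-9
            assert not extrapolated

    def test_noisy_round_trip_median_relative_error(self):
        # Ct noise SD 0.2 cycles over 100 simulated series
        errors = []
        for seed in range(100):
            truth, design = synth.qpcr_preset("dilution", seed=seed, ct_noise_sd=0.2)
            table, _ = synth.make_ct_table(truth, design)
            pairs = [
                (float(a.split("@")[1]), ct)
                for a, ct in zip(table.amplicon, table.ct)
            ]
            curve = fit_standard_curve(pairs)
            for q_true, ct in pairs:
                q_hat, _ = absolute_quantify(ct, curve)
                errors.append(abs(q_hat - q_true) / q_true)
        assert np.median(errors) < 0.15

    def test_extrapolation_flagged(self):
        pairs = [(q, 20 - math.log2(q)) for q in (1, 0.1, 0.01)]
        curve = fit_standard_curve(pairs)
        _, extrapolated = absolute_quantify(10.0, curve)  # Ct below any standard
        assert extrapolated

    def test_missing_ct_gives_nan(self):
        pairs = [(q, 20 - math.log2(q)) for q in (1, 0.1, 0.01)]
        curve = fit_standard_curve(pairs)
        q, _ = absolute_quantify(float("nan"), curve)
        assert math.isnan(q)


class TestRnaseREnrichment:
    @staticmethod
    def _table(d_circ, d_lin, d_ref, noise_seed=None):
        truth = synth.QpcrTruth(
            true_quantities={"circ": 0.5, "lin": 2.0, "ref": 1.0},
            rnaser_circ_decay=d_circ,
            rnaser_linear_decay=d_lin,
        )
        # reference decays with the linear class by construction; to vary it
        # independently, build the table by hand from the closed-form model
        rows = []
        for treatment, factor in (("none", 1.0), ("rnaser", None)):
            for amp, q0, decay in (
                ("circ", 0.5, d_circ),
                ("lin", 2.0, d_lin),
                ("ref", 1.0, d_ref),
            ):
                q = q0 if treatment == "none" else q0 / decay
                ct = 20 - math.log2(q)
                rows.append(("s", amp, treatment, None, 1, ct))
        return pd.DataFrame(rows, columns=qpcr.CT_COLUMNS)

    def test_no_digestion_effect_gives_unit_enrichments(self):
        table = self._table(1, 1, 1)
        row = rnaser_enrichment(table, ["circ"], ["lin"], "ref").iloc[0]
        assert row.circ_enrichment == pytest.approx(1.0)
        assert row.linear_enrichment == pytest.approx(1.0)
        assert row.circ_linear_ratio == pytest.approx(1.0)

    def test_resistant_circle_sixteenfold(self):
        # linear and reference depleted 16-fold, circle untouched
        table = self._table(1, 16, 16)
        row = rnaser_enrichment(table, ["circ"], ["lin"], "ref").iloc[0]
        assert row.circ_enrichment == pytest.approx(16.0)
        assert row.linear_enrichment == pytest.approx(1.0)
        assert row.circ_linear_ratio == pytest.approx(16.0)

    @pytest.mark.parametrize("d_circ,d_lin,d_ref", [(1, 8, 8), (2, 10, 4), (1.5, 6, 1)])
    def test_ratio_equals_dlin_over_dcirc(self, d_circ, d_lin, d_ref):
        # the reference's own decay cancels from the circ/linear ratio
        table = self._table(d_circ, d_lin, d_ref)
        row = rnaser_enrichment(table, ["circ"], ["lin"], "ref").iloc[0]
        assert row.circ_linear_ratio == pytest.approx(d_lin / d_circ, rel=1e-9)

    def test_generator_preset_in_reported_window(self):
        # the preset plants an enrichment inside the 4-14-fold assay window
        truth, design = synth.qpcr_preset("rnaser", seed=0)
        table, _ = synth.make_ct_table(truth, design)
        row = rnaser_enrichment(
            table, ["circ_junction"], ["linear_egfp"], "nupl1"
        ).iloc[0]
        planted = truth.rnaser_linear_decay / truth.rnaser_circ_decay
        assert row.circ_linear_ratio == pytest.approx(planted, rel=1e-9)
        assert 4 <= row.circ_linear_ratio <= 14

    def test_missing_pair_skipped_with_warning(self):
        table = self._table(1, 8, 8)
        table = table[~((table.amplicon == "circ") & (table.treatment == "rnaser"))]
        row = rnaser_enrichment(table, ["circ"], ["lin"], "ref").iloc[0]
        assert row.warning != ""
        assert "circ_linear_ratio" not in row or pd.isna(row.get("circ_linear_ratio"))


class TestNoRtDelta:
    @staticmethod
    def _table(sample_cts, nort_cts, amplicon="amp"):
        rows = []
        for rep, ct in enumerate(sample_cts, start=1):
            rows.append(("s", amplicon, "none", None, rep, ct))
        for rep, ct in enumerate(nort_cts, start=1):
            rows.append(("s", amplicon, "no_rt", None, rep, ct))
        return pd.DataFrame(rows, columns=qpcr.CT_COLUMNS)

    def test_identical_cts_give_zero(self):
        row = no_rt_delta(self._table([24], [24])).iloc[0]
        assert row.delta_ct_mean == pytest.approx(0.0)

    def test_ten_cycle_difference(self):
        row = no_rt_delta(self._table([24], [34])).iloc[0]
        assert row.delta_ct_mean == pytest.approx(10.0)

    def test_replicate_mean_and_sd(self):
        row = no_rt_delta(self._table([20, 20, 20], [30, 31, 32])).iloc[0]
        assert row.delta_ct_mean == pytest.approx(11.0)
        assert row.delta_ct_sd == pytest.approx(1.0)
        assert row.n == 3

    def test_undetermined_no_rt_uses_ceiling_and_flags(self):
        row = no_rt_delta(self._table([24], [float("nan")]), max_cycles=40).iloc[0]
        assert row.delta_ct_mean == pytest.approx(16.0)
        assert row.ceiling_used


class TestPolysomeDistribution:
    @staticmethod
    def _gradient_table(amp_cts, spike_cts):
        rows = []
        for frac, ct in enumerate(amp_cts, start=1):
            rows.append(("s", "amp", "none", frac, 1, ct))
        for frac, ct in enumerate(spike_cts, start=1):
            rows.append(("s", "spike", "none", frac, 1, ct))
        return pd.DataFrame(rows, columns=qpcr.CT_COLUMNS)

    def test_equal_levels_give_uniform_distribution(self):
        table = self._gradient_table([20] * 5, [15] * 5)
        prof = polysome_distribution(table, "spike")["amp"]
        assert prof.abundance == pytest.approx([0.2] * 5)

    def test_invariant_to_uniform_spike_offset(self):
        amp = [20, 21, 19, 22, 20]
        t1 = self._gradient_table(amp, [15] * 5)
        t2 = self._gradient_table(amp, [18] * 5)  # +3 cycles on every spike Ct
        p1 = polysome_distribution(t1, "spike")["amp"]
        p2 = polysome_distribution(t2, "spike")["amp"]
        assert p1.abundance == pytest.approx(p2.abundance)

    def test_sums_to_one(self):
        table = self._gradient_table([20, 25, 18, 30, 22], [15, 16, 14, 15, 15])
        prof = polysome_distribution(table, "spike")["amp"]
        assert prof.abundance.sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_spike_rejects_amplicon(self):
        table = self._gradient_table([20] * 5, [15, 15, float("nan"), 15, 15])
        assert polysome_distribution(table, "spike") == {}

    def test_planted_light_polysome_peak_recovered(self):
        truth, design = synth.qpcr_preset("polysome_light", seed=11)
        table, _ = synth.make_ct_table(truth, design)
        profs = polysome_distribution(
            table, "rluc_spike", synth.DEFAULT_PORTION_MAP
        )
        assert profs["hoxa9_ires"].peak_portion == "light polysome"
        # per-fraction shares equal the planted weight distribution exactly
        w = np.asarray(truth.gradient_weights["hoxa9_ires"], dtype=float)
        assert profs["hoxa9_ires"].abundance == pytest.approx(w / w.sum(), rel=1e-9)


class TestReporterActivity:
    def test_simple_ratio(self):
        assert reporter_activity(100, 50) == pytest.approx(2.0)

    def test_mrna_ratio_halves_activity(self):
        assert reporter_activity(100, 50, mrna_ratio=2) == pytest.approx(1.0)

    def test_reference_scaled_to_one(self):
        acts = reporter_activity(
            {"hbb": 10, "ires": 40}, {"hbb": 5, "ires": 5}, reference="hbb"
        )
        assert acts["hbb"] == pytest.approx(1.0)
        assert acts["ires"] == pytest.approx(4.0)

    def test_zero_fluc_rejected(self):
        with pytest.raises(ValueError):
            reporter_activity(10, 0)
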