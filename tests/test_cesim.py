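"""Yield model, trace simulation, ladder sizing, peak and species calling."""

import numpy as np
import pytest

from plantid import cesim
from plantid.cesim import (
    Electropherogram,
    LadderError,
    PeakCall,
    Product,
    TemplateMixture,
    call_peaks,
    call_species,
    fit_ladder,
    render_trace,
    run_assay,
    simulate_trace,
    simulate_yields,
)
from plantid.design import PrimerCandidate, PrimerPair, Strand
from plantid.multiplex import MultiplexPanel, assign_dyes
from plantid.thermo import Oligo

from conftest import all_nonempty_subsets


def toy_panel(sizes_by_species, half_width=0.5):
    """One-pair-per-species panel with fixed nominal amplicon sizes."""
    rng = np.random.default_rng(1234)
    pairs = {}
    for sp, L in sizes_by_species.items():
        n = 18
        f = PrimerCandidate(
            Oligo("".join(rng.choice(list("ACGT"), size=n))), sp,
            Strand.PLUS, (0, n), 65.0)
        r = PrimerCandidate(
            Oligo("".join(rng.choice(list("ACGT"), size=n))), sp,
            Strand.MINUS, (int(L) - n, int(L)), 65.0)
        pairs[sp] = PrimerPair(f"{sp}.pair", f, r)
    panel = MultiplexPanel(pairs=pairs)
    panel.bins = {p.name: (float(sizes_by_species[sp]), half_width)
                  for sp, p in pairs.items()}
    assign_dyes(panel, min_spacing=0)
    return panel


class TestYields:
    def test_equal_inputs_give_equal_quantities(self):
        panel = toy_panel({"A": 100, "B": 200})
        mix = TemplateMixture({"A": 1.0, "B": 1.0})
        q = simulate_yields(panel, mix)
        assert len(set(q.values())) == 1

    def test_absent_species_yields_zero_product(self):
        panel = toy_panel({"A": 100, "B": 200})
        q = simulate_yields(panel, TemplateMixture({"A": 1.0, "B": 0.0}))
        assert q[panel.pairs["B"].name] == 0.0
        assert q[panel.pairs["A"].name] > 0.0

    def test_degradation_ratio_is_closed_form(self):
        panel = toy_panel({"A": 67, "B": 231})
        mix = TemplateMixture({"A": 1.0, "B": 1.0}, degradation_lambda=300.0)
        q = simulate_yields(panel, mix)
        ratio = q[panel.pairs["A"].name] / q[panel.pairs["B"].name]
        assert ratio == pytest.approx(np.exp(-67 / 300) / np.exp(-231 / 300))

    def test_weights_scale_quantities(self):
        panel = toy_panel({"A": 100, "B": 200})
        panel.efficiency_weight[panel.pairs["A"].name] = 500.0
        panel.efficiency_weight[panel.pairs["B"].name] = 100.0
        q = simulate_yields(panel, TemplateMixture({"A": 1.0, "B": 1.0}))
        assert q[panel.pairs["A"].name] == pytest.approx(
            5 * q[panel.pairs["B"].name])


class TestTrace:
    def test_zero_quantities_leave_primer_channels_flat(self):
        panel = toy_panel({"A": 100})
        eph = simulate_trace({panel.pairs["A"].name: 0.0}, panel,
                             noise_sd=0.0, mobility_sd=0.0, seed=1)
        assert eph.channels["FAM"].max() == 0.0
        assert eph.channels["ROX"].max() > 0.0

    def test_noiseless_single_product_peaks_at_nominal_size(self):
        panel = toy_panel({"A": 100})
        eph = simulate_trace({panel.pairs["A"].name: 1.0}, panel,
                             noise_sd=0.0, mobility_sd=0.0, seed=1)
        peaks = call_peaks(eph)
        assert len(peaks) == 1
        assert peaks[0].measured_size == pytest.approx(100.0, abs=0.01)

    def test_seeded_runs_are_identical(self):
        panel = toy_panel({"A": 100, "B": 140})
        q = simulate_yields(panel, TemplateMixture({"A": 1.0, "B": 0.5}))
        a = simulate_trace(q, panel, seed=77)
        b = simulate_trace(q, panel, seed=77)
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name], b.channels[name])


class TestLadder:
    def test_product_at_ladder_position_measures_ladder_size(self):
        panel = toy_panel({"A": 139})  # 139 is a ladder fragment
        eph = simulate_trace({panel.pairs["A"].name: 1.0}, panel,
                             noise_sd=0.0, mobility_sd=0.0, seed=1)
        peaks = call_peaks(eph)
        assert peaks[0].measured_size == pytest.approx(139.0, abs=1e-6)

    def test_linear_mobility_midpoint_interpolates_to_62_5(self):
        eph = render_trace([Product("FAM", 62.5, 1.0)], noise_sd=0.0)
        cal = fit_ladder(eph)
        # scan exactly midway between the 50 and 75 ladder peaks
        mid_scan = 0.5 * (cal.scans[1] + cal.scans[2])
        assert cal.size_at(mid_scan) == pytest.approx(62.5, abs=1e-6)
        peaks = call_peaks(eph, calibration=cal)
        assert peaks[0].measured_size == pytest.approx(62.5, abs=0.01)

    def test_missing_ladder_fragment_is_ladder_failure(self):
        eph = render_trace([], noise_sd=0.0)
        eph.ladder_sizes = eph.ladder_sizes + [550.0]  # expect one more
        with pytest.raises(LadderError, match="ladder failure"):
            fit_ladder(eph)

    def test_sizes_outside_ladder_range_are_refused(self):
        eph = render_trace([Product("FAM", 20.0, 1.0)], noise_sd=0.0)
        peaks = call_peaks(eph)
        assert peaks == []  # 20 bp is below the 35 bp calibration floor


class TestPeakCalling:
    def test_nine_bp_apart_products_resolve_into_two_calls(self):
        # the 222/231 geometry of the published four-plex
        panel = toy_panel({"A": 222, "B": 231})
        q = {panel.pairs["A"].name: 1.0, panel.pairs["B"].name: 1.0}
        eph = simulate_trace(q, panel, noise_sd=0.0, mobility_sd=0.0, seed=1)
        peaks = call_peaks(eph)
        assert len(peaks) == 2
        sizes = sorted(p.measured_size for p in peaks)
        assert sizes[0] == pytest.approx(222, abs=0.05)
        assert sizes[1] == pytest.approx(231, abs=0.05)

    def test_pure_noise_trace_never_calls_peaks(self):
        panel = toy_panel({"A": 100})
        for seed in range(100):
            eph = simulate_trace({panel.pairs["A"].name: 0.0}, panel,
                                 noise_sd=5.0, seed=seed)
            peaks = call_peaks(eph, min_height=50.0)
            assert peaks == []


class TestSpeciesCalling:
    def bins_panel(self):
        return toy_panel({
            "Hypericum androsaemum": 67,
            "Hypericum athoum": 131,
            "Hypericum perforatum": 222,
            "Hypericum ascyron": 231,
        })

    def test_peaks_at_67_and_222_call_two_species(self):
        panel = self.bins_panel()
        peaks = [PeakCall("FAM", 67.0, 1000.0, 0.0),
                 PeakCall("FAM", 222.4, 800.0, 0.0)]
        report = call_species(peaks, panel)
        assert report.present == {"Hypericum androsaemum",
                                  "Hypericum perforatum"}

    def test_peak_beyond_half_width_is_unassigned(self):
        panel = self.bins_panel()
        report = call_species([PeakCall("FAM", 67.6, 1000.0, 0.0)], panel)
        assert report.present == set()
        assert len(report.unassigned_peaks) == 1

    def test_bin_boundary_is_sharp_noiseless(self):
        panel = toy_panel({"A": 100})
        for dev, expect in ((0.49, True), (0.51, False)):
            eph = render_trace([Product("FAM", 100 + dev, 1.0)], noise_sd=0.0)
            report = call_species(call_peaks(eph), panel)
            assert report.calls["A"] is expect

    def test_equidistant_peak_is_unassigned_with_warning(self):
        panel = toy_panel({"A": 100, "B": 101}, half_width=0.5)
        with pytest.warns(UserWarning, match="equidistant"):
            report = call_species([PeakCall("FAM", 100.5, 900.0, 0.0)], panel)
        assert report.present == set()


class TestEndToEnd:
    def test_round_trip_recovers_simulated_species_exactly(
            self, multiplex_panel):
        species = sorted(multiplex_panel.pairs)
        for subset in all_nonempty_subsets(species):
            mix = TemplateMixture({sp: 1.0 for sp in subset})
            report = run_assay(multiplex_panel, mix, seed=17,
                               noise_sd=0.0, mobility_sd=0.0)
            assert report.present == set(subset)

    def test_peak_height_order_tracks_template_amounts(self, multiplex_panel):
        species = sorted(multiplex_panel.pairs)
        amounts = {sp: a for sp, a in zip(species, (4.0, 1.0, 2.0, 0.5))}
        for seed in range(5):
            report = run_assay(multiplex_panel,
                               TemplateMixture(amounts), seed=seed)
            heights = {sp: report.supporting_peak[sp].height for sp in species}
            order_by_height = sorted(species, key=heights.get, reverse=True)
            order_by_amount = sorted(species, key=amounts.get, reverse=True)
            assert order_by_height == order_by_amount

    def test_nontarget_templates_do_not_change_calls(
            self, synthetic_panel, multiplex_panel):
        targets = sorted(multiplex_panel.pairs)
        base = TemplateMixture({sp: 1.0 for sp in targets[:2]})
        spiked = TemplateMixture({
            **base.amounts,
            **{sp: 2.0 for sp in synthetic_panel.non_targets},
        })
        for seed in (0, 1, 2):
            a = run_assay(multiplex_panel, base, seed=seed)
            b = run_assay(multiplex_panel, spiked, seed=seed)
            assert a.calls == b.calls

    def test_degraded_mixture_favours_short_amplicons(self, multiplex_panel):
        species = sorted(multiplex_panel.pairs)
        mix = TemplateMixture({sp: 1.0 for sp in species},
                              degradation_lambda=300.0)
        q = simulate_yields(multiplex_panel, mix)
        lengths = {multiplex_panel.pairs[sp].name:
                   multiplex_panel.pairs[sp].amplicon_length for sp in species}
        ordered = sorted(q, key=q.get, reverse=True)
        assert [lengths[n] for n in ordered] == sorted(lengths.values())


class TestCsvRoundTrip:
    def test_trace_csv_round_trips(self, tmp_path):
        panel = toy_panel({"A": 100})
        eph = simulate_trace({panel.pairs["A"].name: 1.0}, panel, seed=4)
        path = tmp_path / "trace.csv"
        eph.to_csv(path)
        back = Electropherogram.from_csv(path)
        assert back.ladder_channel == eph.ladder_channel
        for name in eph.channels:
            np.testing.assert_allclose(back.channels[name],
                                       eph.channels[name], atol=1e-3)
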