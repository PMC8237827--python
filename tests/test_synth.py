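"""Synthetic panel and melt-curve generator."""

import numpy as np
import pytest
from dataclasses import replace

from meltfp import (
    DEFAULT_GRID,
    ProcessingConfig,
    TemperatureGrid,
    TransitionSpec,
    extract_fingerprint,
    generate_query_set,
    generate_reference_curves,
    simulate_melt_curve,
)
from meltfp.synth import PanelSpec, make_default_panel
from meltfp import study


class TestDefaultPanel:
    @pytest.mark.parametrize(
        "species,primer,population,expected",
        [
            ("Indo-Pacific bottlenose dolphin", "UBC812", None, (80.0, 81.9, 86.1, 88.0)),
            ("Striped dolphin", "UBC812", None, (79.9, 82.1, 86.1, 88.0)),
            ("Dugong", "UBC848", None, (79.9, 82.6, 87.7)),
            ("Dugong", "UBC848", "GOT", (80.5, 82.6)),
            ("Dwarf sperm whale", "UBC826", None, (78.0, 80.6, 82.6)),
            ("Pygmy sperm whale", "UBC826", None, (78.0, 80.3, 82.4, 87.2)),
        ],
    )
    def test_published_cells_planted_verbatim(self, species, primer, population, expected):
        panel = make_default_panel(seed=1)
        assert panel.tm_list(species, primer, population) == expected

    def test_deterministic_in_seed(self):
        assert make_default_panel(7).to_json() == make_default_panel(7).to_json()
        assert make_default_panel(7).to_json() != make_default_panel(8).to_json()

    def test_shape_and_separation(self, default_panel):
        assert len(default_panel.species) == 16
        assert len(default_panel.primers) == 8
        for cell in default_panel.transitions.values():
            tms = sorted(t.tm for t in cell)
            assert 1 <= len(tms) <= 8
            assert all(b - a >= 0.8 - 1e-9 for a, b in zip(tms, tms[1:]))
            assert all(75.0 <= t <= 90.0 for t in tms)

    def test_json_round_trip(self, default_panel, tmp_path):
        path = tmp_path / "panel.json"
        default_panel.save(path)
        assert PanelSpec.load(path).to_json() == default_panel.to_json()

    def test_validation_rejects_close_transitions(self):
        with pytest.raises(ValueError, match="closer"):
            PanelSpec(
                species=("A",), primers=("P",),
                transitions={("A", "P"): (TransitionSpec(80.0, 1.0),
                                          TransitionSpec(80.3, 1.0))},
            )

    def test_validation_rejects_missing_cell(self):
        with pytest.raises(ValueError, match="missing cell"):
            PanelSpec(species=("A", "B"), primers=("P",),
                      transitions={("A", "P"): (TransitionSpec(80.0, 1.0),)})


class TestSimulateMeltCurve:
    def test_no_transitions_flat_baseline(self):
        c = simulate_melt_curve([], noise_sd=0.0, baseline_slope=0.0,
                                baseline_post_level=5.0)
        assert np.allclose(c.fluorescence, 5.0)

    def test_noiseless_curve_monotone_within_slope(self):
        cell = [TransitionSpec(80.0, 50.0), TransitionSpec(85.0, 45.0)]
        c = simulate_melt_curve(cell, noise_sd=0.0)
        diffs = np.diff(c.fluorescence)
        assert np.all(diffs <= abs(-0.05) * 0.1 + 1e-9)

    def test_closed_form_derivative_of_model(self):
        # raw central difference on the noiseless model: apex exactly at tm,
        # height amplitude/(4 width) = 0.625
        c = simulate_melt_curve([TransitionSpec(80.0, 1.0, 0.4)], noise_sd=0.0,
                                baseline_slope=0.0)
        d = -np.gradient(c.fluorescence, c.temperatures)
        i = int(np.argmax(d))
        assert c.temperatures[i] == pytest.approx(80.0, abs=1e-9)
        assert d[i] == pytest.approx(0.625, rel=0.01)

    def test_pipeline_apex_matches_closed_form(self):
        from meltfp import derivative_curve, normalize_curve
        c = simulate_melt_curve([TransitionSpec(80.0, 1.0, 0.4)], noise_sd=0.0,
                                baseline_slope=0.0)
        dc = derivative_curve(normalize_curve(c))
        i = int(np.argmax(dc.values))
        assert dc.temperatures[i] == pytest.approx(80.0, abs=0.05)
        assert dc.values[i] == pytest.approx(1 / (4 * 0.4), rel=0.01)

    def test_noise_deterministic_in_seed(self):
        cell = [TransitionSpec(80.0, 95.0)]
        a = simulate_melt_curve(cell, noise_sd=0.5, seed=3)
        b = simulate_melt_curve(cell, noise_sd=0.5, seed=3)
        c = simulate_melt_curve(cell, noise_sd=0.5, seed=4)
        assert np.array_equal(a.fluorescence, b.fluorescence)
        assert not np.array_equal(a.fluorescence, c.fluorescence)

    def test_transition_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            simulate_melt_curve([TransitionSpec(96.0, 1.0)])
        with pytest.raises(ValueError, match="grid step"):
            simulate_melt_curve([TransitionSpec(80.0, 1.0, width=0.05)])


class TestReferenceCurves:
    def test_counting(self, noiseless_panel):
        curves = generate_reference_curves(noiseless_panel, replicates_per_cell=3)
        assert len(curves) == 3 * 16 * 8

    def test_replicates_required(self, noiseless_panel):
        with pytest.raises(ValueError):
            generate_reference_curves(noiseless_panel, replicates_per_cell=0)

    def test_zero_noise_round_trip_recovers_planted_tms(self, noiseless_panel):
        curves = generate_reference_curves(noiseless_panel, replicates_per_cell=1)
        for rec in curves:
            fp = extract_fingerprint(rec.curve)
            planted = noiseless_panel.tm_list(rec.species, rec.curve.primer)
            assert len(fp.peaks) == len(planted)
            for got, want in zip(fp.tms, planted):
                assert got == pytest.approx(want, abs=DEFAULT_GRID.step / 2)

    def test_jitter_sd_matches_direct_sampling_oracle(self):
        # one species, one primer, one transition; compare the SD of the
        # recovered Tm over jittered replicates against direct Normal samples
        sd = 0.1
        panel = PanelSpec(
            species=("A",), primers=("P",),
            transitions={("A", "P"): (TransitionSpec(82.0, 95.0),)},
            tm_jitter_sd=sd, amplitude_jitter_cv=0.0, noise_sd=0.0, seed=5,
        )
        curves = generate_reference_curves(panel, replicates_per_cell=200)
        recovered = [extract_fingerprint(r.curve).tms[0] for r in curves]
        oracle = 82.0 + np.random.default_rng(42).normal(0, sd, size=200)
        assert np.std(recovered, ddof=1) == pytest.approx(
            np.std(oracle, ddof=1), abs=0.03)
        assert np.mean(recovered) == pytest.approx(82.0, abs=0.02)


class TestQuerySet:
    def test_study_design_counts(self, small_panel_factory):
        panel = small_panel_factory(2, tm_jitter_sd=0.0, noise_sd=0.0)
        qs = generate_query_set(panel)
        assert len(qs) == 140 * len(panel.primers)
        for pr in panel.primers:
            assert len(qs.for_primer(pr)) == 140
        per_species = {sp: 0 for sp in study.QUERY_COUNTS}
        for rec in qs.for_primer(panel.primers[0]):
            per_species[rec.species] += 1
        assert per_species == study.QUERY_COUNTS

    def test_single_individual(self, small_panel_factory):
        panel = small_panel_factory(2)
        qs = generate_query_set(panel, counts={"Dugong": 1})
        assert len(qs) == len(panel.primers)
        assert {r.species for r in qs} == {"Dugong"}

    def test_negative_and_unknown_counts_rejected(self, small_panel_factory):
        panel = small_panel_factory(2)
        with pytest.raises(ValueError, match=">= 0"):
            generate_query_set(panel, counts={"Dugong": -1})
        with pytest.raises(ValueError, match="not in panel"):
            generate_query_set(panel, counts={"Narwhal": 3})

    def test_deterministic_in_seed(self, small_panel_factory):
        panel = small_panel_factory(2)
        a = generate_query_set(panel, counts={"Dugong": 2}, seed=9)
        b = generate_query_set(panel, counts={"Dugong": 2}, seed=9)
        c = generate_query_set(panel, counts={"Dugong": 2}, seed=10)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.curve.fluorescence, rb.curve.fluorescence)
        assert any(
            not np.array_equal(ra.curve.fluorescence, rc.curve.fluorescence)
            for ra, rc in zip(a, c))

    def test_population_offset_shifts_recovered_peaks(self, small_panel_factory):
        # +0.1 °C per-peak offset moves every recovered peak by +0.1 ± step
        panel = small_panel_factory(3, tm_jitter_sd=0.0, noise_sd=0.0,
                                    amplitude_jitter_cv=0.0)
        base = generate_query_set(panel, counts={"Dugong": 1})
        got = generate_query_set(panel, counts={"Dugong": 1},
                                 populations={"Dugong": "GOT"})
        for pr in ("UBC812", "UBC818", "UBC827"):
            fa = extract_fingerprint(next(r.curve for r in base if r.curve.primer == pr))
            fb = extract_fingerprint(next(r.curve for r in got if r.curve.primer == pr))
            assert len(fa.peaks) == len(fb.peaks)
            for a, b in zip(fa.tms, fb.tms):
                assert b - a == pytest.approx(0.1, abs=DEFAULT_GRID.step)
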