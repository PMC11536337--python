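import numpy as np
import pandas as pd
import pytest

from peepkit.detect import CallSelection
from peepkit.dsp import AudioRecording
from peepkit.features import (MeasurementError, NoQualifyingDataError,
                              apply_inclusion_filters, compute_ici,
                              first_call_contrast, measure_calls,
                              measure_spectral, measure_temporal)
from peepkit.raven import (MANDATORY_COLUMNS, SelectionTableError,
                           read_selection_table, selections_to_frame,
                           write_selection_table)
from peepkit.synth import PopulationSpec, draw_population, render_call, \
    simulate_call_table, synth_recording
from conftest import FS, tone


def _embed(x, offset_s=0.5, total_s=2.0):
    out = np.zeros(int(total_s * FS))
    i0 = int(offset_s * FS)
    out[i0:i0 + x.size] = x
    return AudioRecording(out, FS, recording_id="fix")


class TestTemporal:
    def test_rectangular_call_cd90_and_t95(self):
        # constant-amplitude call: cumulative energy is linear, so the
        # central-90% span is 0.9 CD and the 95% point sits at 95% of CD
        cd = 0.080
        rec = _embed(tone(6724.0, cd))
        sel = CallSelection(0.5, 0.5 + cd, 5000.0, 10000.0)
        cd_m, cd90, t95 = measure_temporal(rec, sel)
        assert cd_m == pytest.approx(cd, abs=1e-12)
        assert cd90 == pytest.approx(0.9 * cd, abs=2e-4)
        assert t95 == pytest.approx(95.0, abs=0.2)

    def test_energy_in_first_half_gives_low_t95(self):
        cd = 0.08
        x = tone(6724.0, cd)
        x[x.size // 2:] = 0.0
        rec = _embed(x)
        sel = CallSelection(0.5, 0.5 + cd, 5000.0, 10000.0)
        _, _, t95 = measure_temporal(rec, sel)
        assert t95 <= 50.0

    def test_generator_t95_recovered_on_clean_call(self):
        target = 0.79
        x = render_call(FS, 0.064, 6724.0, 6440.0, 7153.0, target, amp=0.4)
        rec = _embed(x)
        sel = CallSelection(0.5, 0.5 + 0.064, 5000.0, 10000.0)
        _, _, t95 = measure_temporal(rec, sel)
        assert t95 / 100.0 == pytest.approx(target, abs=0.02)

    def test_zero_energy_selection_raises(self):
        rec = _embed(np.zeros(100))
        sel = CallSelection(1.5, 1.58, 5000.0, 10000.0)
        with pytest.raises(MeasurementError):
            measure_temporal(rec, sel)


class TestSpectral:
    def test_pure_tone_pf_within_one_bin(self):
        rec = _embed(tone(6724.0, 0.08))
        sel = CallSelection(0.5, 0.58, 5000.0, 10000.0)
        pf, lf, hf, fr = measure_spectral(rec, sel)
        bin_w = FS / 1024
        assert abs(pf - 6724.0) <= bin_w
        # a tone's measured width is bounded by the Blackman main lobe,
        # ~4 bins, under both LF/HF definitions
        assert fr <= 4 * bin_w
        pf2, _, _, fr2 = measure_spectral(rec, sel, method="db_down")
        assert pf2 == pf and fr2 <= 4 * bin_w

    def test_flat_sweep_lf_hf_bracket_endpoints(self):
        # constant-amplitude linear sweep 6.4 -> 7.15 kHz
        cd = 0.3
        t = (np.arange(int(cd * FS)) + 0.5) / FS
        f0, f1 = 6400.0, 7150.0
        phase = 2 * np.pi * (f0 * t + 0.5 * (f1 - f0) * t ** 2 / cd)
        rec = _embed(0.5 * np.sin(phase))
        sel = CallSelection(0.5, 0.5 + cd, 5000.0, 10000.0)
        pf, lf, hf, fr = measure_spectral(rec, sel)
        bin_w = FS / 1024
        assert abs(lf - f0) <= 2 * bin_w + 0.025 * (f1 - f0)
        assert abs(hf - f1) <= 2 * bin_w + 0.025 * (f1 - f0)

    def test_fr_identity_on_measured_table(self, rng):
        spec = PopulationSpec(n_males=1, seed=19, noise_db=-np.inf)
        pop = draw_population(spec, rng)
        rec, truth = synth_recording(pop.iloc[0], 25.0, "no clutches", spec,
                                     rng, "R1")
        sels = [CallSelection(r.begin_s, r.end_s, 5000.0, 10000.0)
                for r in truth.itertuples()]
        table = measure_calls(rec, sels)
        assert np.allclose(table["fr_hz"], table["hf_hz"] - table["lf_hz"])
        # clean audio: CD within 2 temporal hops, PF within 2 bins of truth
        assert np.allclose(table["cd_s"], truth["cd_s"], atol=2 * 32 / FS)
        assert np.allclose(table["pf_hz"], truth["pf_hz"], atol=2 * FS / 1024)
        assert np.allclose(table["t95_pct"] / 100, truth["t95_pct"] / 100,
                           atol=0.02)


class TestICI:
    def test_simple_gap_arithmetic(self):
        calls = pd.DataFrame({
            "recording_id": ["r", "r"],
            "begin_s": [0.0, 4.10], "end_s": [0.06, 4.16]})
        out = compute_ici(calls)
        assert out["ici_s"].iloc[0] == pytest.approx(4.04)
        assert np.isnan(out["ici_s"].iloc[1])

    def test_single_call(self):
        calls = pd.DataFrame({"recording_id": ["r"],
                              "begin_s": [1.0], "end_s": [1.06]})
        out = compute_ici(calls)
        assert np.isnan(out["ici_s"].iloc[0])
        assert bool(out["first_of_sequence"].iloc[0])

    def test_sequence_threshold_rule(self):
        # gaps of (3, 25, 3) s with threshold 20 -> sequences (1, 1, 2, 2)
        begins = [0.0, 3.06, 28.12, 31.18]
        calls = pd.DataFrame({"recording_id": "r",
                              "begin_s": begins,
                              "end_s": [b + 0.06 for b in begins]})
        out = compute_ici(calls, seq_gap_threshold=20.0)
        assert out["sequence"].tolist() == [1, 1, 2, 2]
        assert out["first_of_sequence"].tolist() == [True, False, True, False]
        assert np.isnan(out["ici_s"].iloc[1])  # gap across the break

    def test_overlapping_calls_raise(self):
        calls = pd.DataFrame({"recording_id": ["r", "r"],
                              "begin_s": [0.0, 0.03], "end_s": [0.06, 0.09]})
        with pytest.raises(ValueError, match="overlap"):
            compute_ici(calls)


def _toy_table(n_calls, recording="r1", male="m1", n_first_extra=0,
               condition="no clutches"):
    begins = np.arange(n_calls) * 4.0
    df = pd.DataFrame({
        "male_id": male, "recording_id": recording,
        "call_idx": np.arange(n_calls),
        "begin_s": begins, "end_s": begins + 0.06,
        "cd_s": 0.064, "condition": condition,
        "first_of_sequence": [True] + [False] * (n_calls - 1),
    })
    if n_first_extra:
        df.loc[df.index[-n_first_extra:], "first_of_sequence"] = True
    return df


class TestInclusionFilters:
    def test_short_recording_excluded(self):
        table = pd.concat([_toy_table(29, "r1"), _toy_table(30, "r2")],
                          ignore_index=True)
        out = apply_inclusion_filters(table, recordings_per_male=1)
        assert set(out["recording_id"]) == {"r2"}

    def test_thirty_calls_yield_twentyfive(self):
        out = apply_inclusion_filters(_toy_table(30), recordings_per_male=1)
        assert len(out) == 25

    def test_full_synthetic_population_keeps_78_recordings(self):
        spec = PopulationSpec(n_males=26, seed=44)
        tab = simulate_call_table(spec, n_recordings=4,
                                  calls_per_recording=40)
        out = apply_inclusion_filters(tab, drop_brooding=False, seed=1)
        assert out["male_id"].nunique() == 26
        assert out["recording_id"].nunique() == 78  # 3 per male
        assert out.groupby("recording_id").size().min() >= 25

    def test_brooding_recordings_dropped(self):
        table = pd.concat(
            [_toy_table(30, "r1", condition="brooding"),
             _toy_table(30, "r2", condition="guarding")], ignore_index=True)
        out = apply_inclusion_filters(table, recordings_per_male=1)
        assert set(out["recording_id"]) == {"r2"}

    def test_idempotent(self):
        spec = PopulationSpec(n_males=8, seed=45)
        tab = simulate_call_table(spec, 3, 35)
        once = apply_inclusion_filters(tab, drop_brooding=False, seed=3)
        twice = apply_inclusion_filters(once, drop_brooding=False, seed=3)
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))

    def test_empty_result_raises(self):
        with pytest.raises(NoQualifyingDataError):
            apply_inclusion_filters(_toy_table(10))


class TestFirstCallContrast:
    def test_identical_groups_give_t_zero(self):
        df = pd.DataFrame({"cd_s": [0.06] * 10,
                           "first_of_sequence": [True] * 5 + [False] * 5})
        t, dof, p = first_call_contrast(df, amplitude_col=None)["duration"]
        assert t == 0.0 and p == 1.0

    def test_generator_contrast_detected(self):
        # first-call duration ratio < 1: strongly negative Welch t at n ~ 200
        n_sig = 0
        for seed in range(5):
            spec = PopulationSpec(n_males=2, seed=200 + seed,
                                  seq_break_prob=0.12)
            tab = simulate_call_table(spec, 3, 35)
            t, dof, p = first_call_contrast(tab)["duration"]
            n_sig += (t < 0) and (p < 0.001)
        assert n_sig == 5

    def test_amplitude_contrast_negative(self):
        spec = PopulationSpec(n_males=3, seed=77, seq_break_prob=0.12)
        tab = simulate_call_table(spec, 3, 35)
        t, dof, p = first_call_contrast(tab)["amplitude"]
        assert t < 0 and p < 0.01


class TestSelectionTables:
    def _sels(self):
        return [CallSelection(0.5, 0.56, 5000.0, 10000.0),
                CallSelection(4.1, 4.17, 5000.0, 10000.0)]

    def test_round_trip_lossless(self, tmp_path):
        frame = selections_to_frame(self._sels())
        frame["Notes"] = ["a", "b"]  # unknown column preserved
        path = tmp_path / "sel.txt"
        write_selection_table(frame, path)
        back = read_selection_table(path)
        assert list(back.columns) == list(frame.columns)
        assert np.allclose(back["Begin Time (s)"], frame["Begin Time (s)"],
                           atol=1e-9)
        assert back["Notes"].tolist() == ["a", "b"]

    def test_missing_columns_named_in_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("Selection\tView\n1\tSpectrogram 1\n")
        with pytest.raises(SelectionTableError, match="Begin Time"):
            read_selection_table(path)

    def test_comma_decimals_rejected(self, tmp_path):
        path = tmp_path / "commas.txt"
        header = "\t".join(MANDATORY_COLUMNS)
        path.write_text(header + "\n1\tSpectrogram 1\t1\t0,5\t0,56\t5000\t10000\n")
        with pytest.raises(SelectionTableError, match="comma"):
            read_selection_table(path)

    def test_hand_written_fixture_parses_exactly(self, tmp_path):
        path = tmp_path / "hand.txt"
        header = "\t".join(MANDATORY_COLUMNS)
        path.write_text(header + "\n"
                        "1\tSpectrogram 1\t1\t0.512345\t0.576543\t5000\t10000\n"
                        "2\tSpectrogram 1\t1\t4.100000\t4.165432\t5000\t10000\n")
        df = read_selection_table(path)
        assert df["Begin Time (s)"].iloc[0] == pytest.approx(0.512345, abs=1e-6)
        assert df["End Time (s)"].iloc[1] == pytest.approx(4.165432, abs=1e-6)
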