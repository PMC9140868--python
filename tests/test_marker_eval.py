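"""Verdict assignment, sex calls and panel recommendation."""

import itertools

import pytest

from zwmarker.copy_comparison import CopyPairReport
from zwmarker.gel_model import GelConfig, band_pattern
from zwmarker.marker_eval import (
    MarkerVerdict,
    evaluate_marker,
    recommend_panel,
    sex_call,
    species_report_md,
    verdicts_to_frame,
)


def _pair(marker, z, second=None, partial=False, location=None, species="S"):
    if second is None and not partial:
        return CopyPairReport(marker, species, "Z_SYN", z, None, None, False, "absent", None, None)
    loc = location or "W"
    if partial:
        return CopyPairReport(marker, species, "Z_SYN", z, "w", second, True, loc, None, None)
    delta = abs(z - second)
    return CopyPairReport(
        marker, species, "Z_SYN", z, "w", second, False, loc,
        delta, (z > second) if delta else None,
    )


class TestEvaluateMarker:
    def test_large_polymorphism_informative_at_1pct(self):
        v = evaluate_marker(_pair("M7", 923, 510))
        assert v.verdict == "informative"
        assert v.gel_pct_required == 1
        assert v.delta_l == 413

    def test_absent_second_copy_is_z_only(self):
        v = evaluate_marker(_pair("M7", 923))
        assert v.verdict == "z_only"

    def test_small_polymorphism_needs_3pct(self):
        v = evaluate_marker(_pair("M1", 367, 378))
        assert v.verdict == "informative"
        assert v.gel_pct_required == 3

    def test_zero_delta_unresolvable(self):
        v = evaluate_marker(_pair("M1", 364, 364))
        assert v.verdict == "unresolvable_polymorphism"

    def test_partial_copy_only(self):
        v = evaluate_marker(_pair("M7", 923, 526, partial=True))
        assert v.verdict == "partial_copy_only"

    def test_no_amplicon_not_found(self):
        v = evaluate_marker(None, marker_id="M6", species_id="S1")
        assert v.verdict == "not_found"
        assert v.marker_id == "M6"

    def test_nonspecific_band_in_diagnostic_window_confounds(self):
        v = evaluate_marker(_pair("M3", 2997, 623), nonspecific_lengths=[600])
        assert v.verdict == "confounded"
        assert any("600" in n for n in v.notes)

    def test_separable_nonspecific_band_noted_not_confounding(self):
        v = evaluate_marker(_pair("M7", 923, 510), nonspecific_lengths=[2000])
        assert v.verdict == "informative"
        assert any("2000" in n for n in v.notes)

    def test_w_dominant_design_confounded_without_control(self):
        v = evaluate_marker(_pair("M6", 390, None), w_band_only=True)
        assert v.verdict == "confounded"

    def test_verdict_total_over_report_space(self):
        reports = [
            _pair("M", 500),
            _pair("M", 500, 450),
            _pair("M", 500, 500),
            _pair("M", 500, 300, partial=True),
            None,
        ]
        for rep in reports:
            v = evaluate_marker(rep, marker_id="M")
            assert v.verdict in (
                "informative", "z_only", "unresolvable_polymorphism",
                "partial_copy_only", "not_found", "confounded",
            )

    def test_informative_requires_standard_gel(self):
        with pytest.raises(ValueError):
            MarkerVerdict("M", "S", "informative", gel_pct_required=None)


class TestSexCall:
    def _verdict(self, z=923, w=510):
        return evaluate_marker(_pair("M7", z, w))

    def _lane(self, lane_id, lengths, pct=1.0):
        return band_pattern(lane_id, lengths, GelConfig().at(pct), 60)

    def test_two_separable_bands_female(self):
        call = sex_call(self._lane("f1", [923, 510]), self._verdict())
        assert call.call == "female"
        assert call.band_count == 2

    def test_single_band_informative_male(self):
        call = sex_call(self._lane("m1", [923]), self._verdict())
        assert call.call == "male"

    def test_single_band_z_only_indeterminate(self):
        v = evaluate_marker(_pair("M7", 923))
        call = sex_call(self._lane("i1", [923]), v)
        assert call.call == "indeterminate"
        assert "z_only" in call.reason

    def test_unresolvable_marker_never_calls_male(self):
        v = evaluate_marker(_pair("M1", 364, 364))
        call = sex_call(self._lane("i2", [364]), v)
        assert call.call == "indeterminate"

    def test_no_diagnostic_band_indeterminate(self):
        call = sex_call(self._lane("i3", [2000]), self._verdict())
        assert call.call == "indeterminate"


class TestRecommendPanel:
    def _grid(self):
        verdicts = []
        for sp in [f"S{i}" for i in range(1, 15)]:
            # NIPBL-like marker: absent second copy in S1, informative elsewhere
            verdicts.append(
                evaluate_marker(
                    _pair("M7", 923, species=sp)
                    if sp == "S1"
                    else _pair("M7", 923, 510, species=sp)
                )
            )
            # huge-delta marker, but confounded outside S1 by a nonspecific
            # product comigrating with its 623 bp band
            verdicts.append(
                evaluate_marker(
                    _pair("M3", 2997, 623, species=sp),
                    nonspecific_lengths=[] if sp == "S1" else [600],
                )
            )
            # small-delta marker: 3% gel
            verdicts.append(evaluate_marker(_pair("M1", 367, 378, species=sp)))
        return verdicts

    def test_reconstructed_grid_prefers_easiest_marker(self):
        panel = recommend_panel(self._grid())
        for sp, picks in panel.items():
            if sp == "S1":
                assert picks[0].marker_id == "M3"
                assert "M7" not in [p.marker_id for p in picks]
            else:
                assert picks[0].marker_id == "M7"

    def test_order_invariant_under_permutation(self):
        grid = self._grid()[:6]
        rankings = {
            tuple((sp, tuple(v.marker_id for v in picks)) for sp, picks in recommend_panel(p).items())
            for p in itertools.permutations(grid)
        }
        assert len(rankings) == 1

    def test_all_z_only_grid_empty_recommendation(self):
        verdicts = [evaluate_marker(_pair("M7", 923, species=f"S{i}")) for i in (1, 2)]
        panel = recommend_panel(verdicts)
        assert all(picks == [] for picks in panel.values())
        report = species_report_md(verdicts)
        assert "none" in report

    def test_single_informative_marker_recommended(self):
        v = evaluate_marker(_pair("M4", 504, 461))
        assert recommend_panel([v])["S"][0].marker_id == "M4"

    def test_frame_columns(self):
        df = verdicts_to_frame(self._grid())
        assert list(df.columns) == [
            "species", "marker", "verdict", "gel_pct", "z_length",
            "second_length", "delta_l", "notes",
        ]
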