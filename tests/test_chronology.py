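"""Segment chaining, local DSR, CFT/Ci/Cc and event dating."""

import json

import numpy as np
import pytest

from odontochron import (
    ChainError,
    CrossStriationRun,
    Point2D,
    build_segment_chain,
    crown_chronology,
    local_dsr,
    locate_event_day,
    round_days,
    simulate_tooth,
)
from odontochron.synthetic import default_params
from odontochron.tracings import PrismSegmentTrace, read_tracing, section_to_dict, write_tracing


def _run(i, length, n):
    return CrossStriationRun(segment_index=i, run_length=length, n_striations=n)


class TestLocalDSR:
    def test_single_run(self):
        assert local_dsr([_run(1, 19.02, 6)]) == pytest.approx(3.17)

    def test_runs_averaged_unweighted(self):
        assert local_dsr([_run(1, 19.02, 6), _run(1, 12.48, 4)]) == pytest.approx(3.145)

    def test_empty_is_error(self):
        with pytest.raises(ChainError, match="no DSR runs"):
            local_dsr([])

    def test_out_of_band_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            local_dsr([_run(1, 90.0, 6)])

    def test_monte_carlo_recovery(self):
        """100 noisy runs at true DSR 3.17 estimate it within 0.03."""
        rng = np.random.default_rng(7)
        runs = []
        for _ in range(100):
            n = int(rng.integers(6, 13))
            runs.append(_run(1, n * 3.17 * (1 + 0.03 * rng.standard_normal()), n))
        assert local_dsr(runs) == pytest.approx(3.17, abs=0.03)


class TestChain:
    def test_exact_chaining_on_simulated_tooth(self, noiseless_tooth):
        section, truth = noiseless_tooth
        chain = build_segment_chain(section)
        assert len(chain) == len(truth.segment_times) - 1
        arcs = [s.edj_start_arc for s in chain] + [chain[-1].edj_end_arc]
        assert np.all(np.diff(arcs) > 0)
        # chained arcs agree with the recruitment-front truth
        assert np.allclose(arcs, truth.segment_arcs, atol=0.5)

    def test_displaced_start_beyond_tolerance_is_error(self, noiseless_tooth):
        section, _ = noiseless_tooth
        victim = section.prisms[2]
        moved = Point2D(victim.start_on_edj.x + 60.0, victim.start_on_edj.y)
        section_bad = _with_prism(section, 2, start_on_edj=moved)
        with pytest.raises(ChainError, match=f"segment {victim.index}"):
            build_segment_chain(section_bad, tolerance=50.0)

    def test_worn_horn_chain_starts_at_first_surviving_prism(self):
        section, truth = simulate_tooth(default_params(seed=9, wear_truncation=500.0))
        assert section.flags.worn_horn
        assert section.prisms[0].index > 1
        result = crown_chronology(section)
        assert "worn_start" in result.qc_flags
        assert result.cft_is_minimum and result.cft_excluded


def _with_prism(section, pos, **overrides):
    import copy

    new = copy.copy(section)
    prisms = list(section.prisms)
    old = prisms[pos]
    prisms[pos] = PrismSegmentTrace(
        index=old.index,
        path=overrides.get("path", old.path),
        start_on_edj=overrides.get("start_on_edj", old.start_on_edj),
        terminal_stria=old.terminal_stria,
    )
    new.prisms = prisms
    return new


class TestCrownChronology:
    def test_two_segment_arithmetic(self, noiseless_tooth, tmp_path):
        """Segment days are length / local DSR and sum to CFT."""
        section, _ = noiseless_tooth
        doc = section_to_dict(section)
        doc["prisms"] = doc["prisms"][:2]
        keep = {1, 2}
        doc["runs"] = [
            {"segment_index": 1, "run_length": 32.0, "n_striations": 10},
            {"segment_index": 2, "run_length": 31.25, "n_striations": 10},
        ]
        doc["striae"] = [s for s in doc["striae"] if s["id"] in ("T1", "T2")]
        path = tmp_path / "two.json"
        path.write_text(json.dumps(doc))
        with pytest.warns(UserWarning, match="no neonatal"):
            two = read_tracing(path)
        # force both prisms to exactly 200 µm is already true by construction
        result = crown_chronology(two)
        expected = two.prisms[0].path.arc_length / 3.2 + two.prisms[1].path.arc_length / 3.125
        assert result.cft == pytest.approx(expected, rel=1e-12)
        assert result.cft_rounded == round_days(expected)

    def test_noise_free_identity(self, noiseless_tooth):
        """Zero-noise pipeline recovers the ground truth to < 0.5 day."""
        section, truth = noiseless_tooth
        result = crown_chronology(section)
        assert result.cft == pytest.approx(truth.cft, abs=0.5)
        assert result.ci == pytest.approx(truth.ci, abs=0.5)
        assert result.cc == pytest.approx(truth.cc, abs=0.5)
        ages = dict(result.event_ages)
        for sid, rel in truth.al_true_ages.items():
            assert ages[sid] == pytest.approx(rel, abs=0.5)

    def test_conservation_and_monotonicity(self, cohort20_results):
        for result, _ in cohort20_results:
            assert result.ci + result.cc == pytest.approx(result.cft, abs=1e-9)
            cum = [s.cum_days_start for s in result.segments] + [result.segments[-1].cum_days_end]
            assert np.all(np.diff(cum) > 0)
            assert result.cft == pytest.approx(
                sum(s.days for s in result.segments), rel=1e-12
            )

    def test_scale_equivariance(self, noiseless_tooth, tmp_path):
        """Multiplying every length by k leaves all day values unchanged."""
        section, _ = noiseless_tooth
        base = crown_chronology(section)
        k = 2.7
        doc = section_to_dict(section)
        for key in ("edj", "enamel_outline"):
            doc[key] = [[x * k, y * k] for x, y in doc[key]]
        for p in doc["prisms"]:
            p["path"] = [[x * k, y * k] for x, y in p["path"]]
            p["start_on_edj"] = [c * k for c in p["start_on_edj"]]
        for s in doc["striae"]:
            s["path"] = [[x * k, y * k] for x, y in s["path"]]
        for r in doc["runs"]:
            r["run_length"] *= k
        path = tmp_path / "scaled.json"
        path.write_text(json.dumps(doc))
        scaled = crown_chronology(read_tracing(path), tolerance=25.0 * k)
        assert scaled.cft == pytest.approx(base.cft, rel=1e-6)
        assert scaled.ci == pytest.approx(base.ci, rel=1e-6)

    def test_missing_nnl_restricts_to_cft(self, noiseless_tooth, tmp_path):
        section, _ = noiseless_tooth
        doc = section_to_dict(section)
        doc["striae"] = [s for s in doc["striae"] if s["kind"] != "neonatal"]
        path = tmp_path / "no_nnl.json"
        path.write_text(json.dumps(doc))
        with pytest.warns(UserWarning):
            result = crown_chronology(read_tracing(path))
        assert result.ci is None and result.cc is None
        assert "no_neonatal_line" in result.qc_flags
        assert result.cft > 0

    def test_dsr_means_split_at_birth(self, noiseless_tooth):
        section, truth = noiseless_tooth
        result = crown_chronology(section)
        # generator plants a higher prenatal than postnatal inner DSR
        assert result.dsr_prenatal_mean > result.dsr_postnatal_mean
        assert result.dsr_overall_mean == pytest.approx(
            truth.params.dsr_inner_mean, abs=0.2
        )


class TestEventDating:
    def test_terminal_stria_dates_to_segment_boundary(self, noiseless_tooth):
        """A stria crossing exactly at a boundary gets that cumulative day."""
        section, _ = noiseless_tooth
        result = crown_chronology(section)
        t1 = next(s for s in section.striae if s.id == "T1")
        day, _ = locate_event_day(result.segments, t1)
        assert day == pytest.approx(result.segments[0].cum_days_end, abs=0.05)

    def test_linear_interpolation_within_segment(self):
        """Midpoint crossing of a segment dates to half its duration."""
        from odontochron.chronology import SegmentChronology
        from odontochron.geometry import Polyline
        from odontochron.tracings import StriaTrace

        seg = SegmentChronology(
            index=1, length=200.0, edj_start_arc=0.0, edj_end_arc=300.0,
            path=Polyline([(0.0, 0.0), (0.0, 200.0)]),
        )
        seg.days, seg.cum_days_start, seg.cum_days_end = 63.1, 100.0, 163.1
        stria = StriaTrace(id="AL", kind="accentuated",
                           path=Polyline([(-10.0, 100.0), (10.0, 100.0)]))
        day, flags = locate_event_day([seg], stria)
        assert day == pytest.approx(100.0 + 0.5 * 63.1)
        assert not flags

    def test_no_intersection_is_error(self):
        from odontochron.chronology import SegmentChronology
        from odontochron.geometry import Polyline
        from odontochron.tracings import StriaTrace

        seg = SegmentChronology(
            index=1, length=200.0, edj_start_arc=0.0, edj_end_arc=300.0,
            path=Polyline([(0.0, 0.0), (0.0, 200.0)]),
        )
        seg.days, seg.cum_days_start, seg.cum_days_end = 60.0, 0.0, 60.0
        far = StriaTrace(id="far", kind="accentuated",
                         path=Polyline([(50.0, 0.0), (60.0, 10.0)]))
        with pytest.raises(ChainError, match="far"):
            locate_event_day([seg], far)

    def test_accentuated_ages_recovered_relative_to_birth(self, cohort20_results):
        """Planted stress days (-40, +120 around birth) come back within ±2 d."""
        errors = []
        for result, truth in cohort20_results:
            ages = dict(result.event_ages)
            for sid, rel in truth.al_true_ages.items():
                errors.append(ages[sid] - rel)
        assert len(errors) > 20
        assert np.max(np.abs(errors)) <= 2.0
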