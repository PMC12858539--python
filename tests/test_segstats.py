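"""Segment aggregation, reference normalization, labels and plaque sums."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coroshear import (
    ValidationError,
    aggregate_segment,
    build_cohort_table,
    define_segments,
    label_outcome,
    normalize_to_reference,
    plaque_arithmetic,
)
from coroshear.geometry import REFERENCE_ID, assign_vertices_to_segments
from coroshear.indices import IndexMaps
from coroshear.segstats import SegmentSummary
from tests.conftest import MU, Q


def _summary(values: dict) -> SegmentSummary:
    return SegmentSummary(
        segment_id=1,
        stats={k: {"min": v[0], "max": v[1], "mean": v[2]} for k, v in values.items()},
        counts={k: 10 for k in values},
        flagged={k: 0 for k in values},
    )


@pytest.fixture(scope="module")
def aggregated(stenotic_tube, pulsatile_waveform, hemo_config):
    from coroshear import compute_index_maps, solve_reduced_order, stenosis_metrics

    wall, vol = solve_reduced_order(stenotic_tube, pulsatile_waveform, hemo_config)
    maps = compute_index_maps(wall, vol, stenotic_tube)
    metrics = stenosis_metrics(stenotic_tube, 0.0)
    segdef = define_segments(stenotic_tube, metrics["lesion_extent"], 3e-3)
    a_s = assign_vertices_to_segments(stenotic_tube.vertex_s, segdef)
    a_v = assign_vertices_to_segments(vol.param_s, segdef)
    summaries = aggregate_segment(
        maps,
        a_s,
        segdef,
        surface_weights=stenotic_tube.vertex_areas(),
        volume_assignment=a_v,
        volume_weights=np.maximum(vol.param_r, 1e-12),
    )
    return maps, metrics, segdef, summaries


class TestAggregation:
    def test_constant_field_collapses(self, uniform_tube):
        maps = IndexMaps(surface={"tawss": np.full(len(uniform_tube.vertex_s), 2.0)})
        segdef = define_segments(uniform_tube, (20e-3, 32e-3), 3e-3)
        a = assign_vertices_to_segments(uniform_tube.vertex_s, segdef)
        out = aggregate_segment(maps, a, segdef)
        for s in out:
            assert s.stats["tawss"] == {"min": 2.0, "max": 2.0, "mean": 2.0}

    def test_simple_min_max_mean(self, uniform_tube):
        vals = np.full(len(uniform_tube.vertex_s), np.nan)
        segdef = define_segments(uniform_tube, (20e-3, 22e-3), 2e-3)
        a = assign_vertices_to_segments(uniform_tube.vertex_s, segdef)
        members = np.flatnonzero(a == 1)[:3]
        vals[members] = [1.0, 2.0, 3.0]
        maps = IndexMaps(surface={"x": vals})
        out = aggregate_segment(maps, a, segdef, surface_weights=np.ones_like(vals))
        seg = next(s for s in out if s.segment_id == 1)
        assert seg.stats["x"] == {"min": 1.0, "max": 3.0, "mean": 2.0}
        assert seg.counts["x"] == 3

    def test_max_tawss_in_throat_segment(self, aggregated, stenotic_tube):
        maps, metrics, segdef, summaries = aggregated
        s_mla = metrics["s_MLA"]
        k = next(
            i + 1
            for i, (a, b) in enumerate(segdef.sub_intervals)
            if a <= s_mla <= b
        )
        seg = next(s for s in summaries if s.segment_id == k)
        r_min = stenotic_tube.radius.min()
        tau_peak = 4 * MU * Q / (np.pi * r_min**3)
        assert seg.stats["tawss"]["max"] == pytest.approx(tau_peak, rel=0.01)

    def test_flagged_values_excluded(self, uniform_tube):
        vals = np.full(len(uniform_tube.vertex_s), 1.0)
        vals[:10] = np.nan
        maps = IndexMaps(surface={"x": vals})
        segdef = define_segments(uniform_tube, (20e-3, 32e-3), 3e-3)
        a = assign_vertices_to_segments(uniform_tube.vertex_s, segdef)
        out = aggregate_segment(maps, a, segdef)
        total_flagged = sum(s.flagged["x"] for s in out)
        assert total_flagged == int(np.isnan(vals[a >= 0]).sum())

    def test_refinement_consistency(self, uniform_tube):
        """Splitting a segment and recombining weighted means is lossless."""
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.5, 2.0, len(uniform_tube.vertex_s))
        w = uniform_tube.vertex_areas()
        maps = IndexMaps(surface={"x": vals})
        coarse = define_segments(uniform_tube, (20e-3, 24e-3), 4e-3)
        fine = define_segments(uniform_tube, (20e-3, 24e-3), 2e-3)
        a_c = assign_vertices_to_segments(uniform_tube.vertex_s, coarse)
        a_f = assign_vertices_to_segments(uniform_tube.vertex_s, fine)
        out_c = aggregate_segment(maps, a_c, coarse, surface_weights=w)
        out_f = aggregate_segment(maps, a_f, fine, surface_weights=w)
        big = next(s for s in out_c if s.segment_id == 1)
        parts = [s for s in out_f if s.segment_id >= 1]
        wsum = [w[a_f == s.segment_id].sum() for s in parts]
        recombined = sum(
            s.stats["x"]["mean"] * ws for s, ws in zip(parts, wsum)
        ) / sum(wsum)
        assert recombined == pytest.approx(big.stats["x"]["mean"], abs=1e-12)


class TestNormalization:
    def test_simple_ratio(self):
        les = _summary({"tawss": (1.0, 3.0, 2.0)})
        ref = _summary({"tawss": (0.8, 2.0, 1.6)})
        norm = normalize_to_reference(les, ref)
        assert norm.values["tawss"]["mean"] == pytest.approx(1.25)
        assert norm.values["tawss"]["min"] == pytest.approx(1.25)
        assert norm.values["tawss"]["max"] == pytest.approx(1.5)

    def test_self_normalization_is_unity(self):
        ref = _summary({"tawss": (1.0, 3.0, 2.0), "osi": (0.1, 0.3, 0.2)})
        norm = normalize_to_reference(ref, ref)
        for stats in norm.values.values():
            assert all(v == 1.0 for v in stats.values())

    def test_zero_reference_flagged_not_divided(self):
        les = _summary({"osi": (0.0, 0.2, 0.1)})
        ref = _summary({"osi": (0.0, 0.1, 0.05)})  # steady reference: min OSI 0
        norm = normalize_to_reference(les, ref)
        assert np.isnan(norm.values["osi"]["min"])
        assert ("osi", "min") in norm.flagged

    def test_scale_invariance(self):
        les = _summary({"x": (1.0, 4.0, 2.5)})
        ref = _summary({"x": (0.5, 2.0, 1.0)})
        n1 = normalize_to_reference(les, ref)
        c = 7.3
        les2 = _summary({"x": (c * 1.0, c * 4.0, c * 2.5)})
        ref2 = _summary({"x": (c * 0.5, c * 2.0, c * 1.0)})
        n2 = normalize_to_reference(les2, ref2)
        for stat in ("min", "max", "mean"):
            assert n2.values["x"][stat] == pytest.approx(n1.values["x"][stat], rel=1e-12)

    def test_mismatched_panels_rejected(self):
        with pytest.raises(ValidationError):
            normalize_to_reference(_summary({"a": (1, 2, 1.5)}), _summary({"b": (1, 2, 1.5)}))


class TestOutcomeLabels:
    @pytest.mark.parametrize(
        "dds,expected",
        [
            (5.0, "progression"),
            (4.99, "stable"),
            (-4.99, "stable"),
            (-5.0, "regression"),
            (0.0, "stable"),
            (17.2, "progression"),
            (-12.0, "regression"),
        ],
    )
    def test_threshold_boundaries(self, dds, expected):
        assert label_outcome(dds) == expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(-100, 100, allow_nan=False))
    def test_every_value_gets_exactly_one_label(self, dds):
        assert label_outcome(dds) in {"progression", "stable", "regression"}

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            label_outcome(float("nan"))


class TestPlaqueArithmetic:
    def test_printed_sums(self):
        out = plaque_arithmetic(10, 20, 5)
        assert out["total"] == 35
        assert out["non_calcified"] == 30

    def test_all_zero(self):
        out = plaque_arithmetic(0, 0, 0)
        assert out["total"] == 0 and out["non_calcified"] == 0

    def test_stenosis_degree_from_areas(self):
        out = plaque_arithmetic(1, 1, 1, proximal_area=8.0, mla=2.0)
        assert out["stenosis_degree"] == pytest.approx(75.0)
        out = plaque_arithmetic(1, 1, 1, proximal_area=10.0, mla=5.0)
        assert out["stenosis_degree"] == pytest.approx(50.0)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValidationError):
            plaque_arithmetic(-1, 0, 0)


class TestCohortTable:
    def _records(self, n):
        recs = []
        for i in range(n):
            recs.append(
                {
                    "patient_id": i // 10,
                    "vessel_id": i // 6,
                    "segment_id": i % 6,
                    "normalized": type(
                        "N", (), {"values": {"tawss": {"min": 1.0, "max": 2.0, "mean": 1.5}}}
                    )(),
                    "delta_DS_percent": 6.0 if i % 2 else -6.0,
                }
            )
        return recs

    def test_column_names_follow_convention(self):
        df = build_cohort_table(self._records(6))
        for col in ("N.Min.TAWSS", "N.Max.TAWSS", "N.Ave.TAWSS"):
            assert col in df.columns
        assert set(df["label"]) <= {"progression", "stable", "regression"}

    def test_duplicate_keys_rejected(self):
        recs = self._records(2)
        recs[1]["vessel_id"] = recs[0]["vessel_id"]
        recs[1]["segment_id"] = recs[0]["segment_id"]
        with pytest.raises(ValidationError):
            build_cohort_table(recs)

    def test_empty_input_keeps_schema(self):
        df = build_cohort_table([])
        assert len(df) == 0
        assert "label" in df.columns

    def test_csv_round_trip(self, tmp_path):
        df = build_cohort_table(self._records(12))
        p = tmp_path / "cohort.csv"
        df.to_csv(p, index=False)
        back = pd.read_csv(p)
        pd.testing.assert_frame_equal(back, df, check_dtype=False)
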