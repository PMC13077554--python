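"""CMEA / CCMEA accumulation: the exposure ratio and its streaming sum."""

import numpy as np
import pytest

from ccmea.metric import (
    accumulate,
    cmea,
    oracle_pipeline,
    score_directory,
    score_frames,
    score_video,
)
from ccmea.synthetic import FramePhantomSpec, generate_procedure
from ccmea.types import Frame, FrameClass, FrameMetric, ProcedureFrame

Q, B, C, V = (
    FrameClass.QUALIFIED,
    FrameClass.BLURRED,
    FrameClass.CHROMOENDOSCOPY,
    FrameClass.IN_VITRO,
)


def synthetic_item(cmea_value=0.5, label=Q, n=16):
    """Fabricated truth-carrying frame with an exact CMEA, no rendering."""
    side = int(np.sqrt(n))
    view = np.ones((side, side), dtype=bool)
    exposure = np.zeros((side, side), dtype=bool)
    exposure.ravel()[: int(round(cmea_value * n))] = True
    img = np.full((side, side, 3), 0.5, dtype=np.float32)
    return ProcedureFrame(
        frame=Frame(image=img),
        view_truth=view,
        exposure_truth=exposure,
        label=label,
        cmea_truth=float(exposure.sum()) / n,
    )


class TestCmea:
    def test_full_exposure(self):
        v = np.ones((10, 10), bool)
        assert cmea(v, v) == 1.0

    def test_empty_exposure(self):
        v = np.ones((10, 10), bool)
        assert cmea(np.zeros_like(v), v) == 0.0

    def test_half_exposure_pixel_counts(self):
        view = np.zeros((100, 100), bool)
        view.ravel()[:10000] = True  # 10000 px view
        exposure = np.zeros_like(view)
        exposure.ravel()[:5000] = True
        assert cmea(exposure, view) == 0.5

    def test_empty_view_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cmea(np.zeros((5, 5), bool), np.zeros((5, 5), bool))


class TestFrameMetricInvariants:
    def test_qualified_requires_cmea(self):
        with pytest.raises(ValueError):
            FrameMetric(frame_index=0, frame_class=Q, cmea=None)

    def test_unqualified_forbids_cmea(self):
        with pytest.raises(ValueError):
            FrameMetric(frame_index=0, frame_class=B, cmea=0.5)

    def test_cmea_bounds(self):
        with pytest.raises(ValueError):
            FrameMetric(frame_index=0, frame_class=Q, cmea=1.5)


class TestAccumulate:
    def test_threshold_reached_by_construction(self):
        """4000 qualified frames at CMEA 0.5 accumulate to exactly 2000 and
        a tie with the threshold counts as qualified."""
        stream = (synthetic_item(0.5) for _ in range(4000))
        record = accumulate(stream, threshold=2000.0, **oracle_pipeline())
        assert record.ccmea == 2000.0
        assert record.qualified_flag is True

    def test_chromoendoscopy_suspension(self):
        items = [synthetic_item(0.5)] * 10
        for i in (2, 4, 6, 8, 10):
            items.insert(i, synthetic_item(0.75, label=C))
        record = accumulate(items, **oracle_pipeline())
        assert record.ccmea == 5.0
        assert record.n_chromo == 5 and record.n_qualified == 10

    def test_unqualified_contributes_zero(self):
        items = [synthetic_item(0.25), synthetic_item(0.5, label=B), synthetic_item(0.25, label=V)]
        record = accumulate(items, **oracle_pipeline())
        assert record.ccmea == 0.25  # only the single qualified frame counts
        assert record.n_other_unqualified == 2

    def test_additivity_over_concatenation(self):
        a = [synthetic_item(v) for v in (0.25, 0.5, 0.75)]
        b = [synthetic_item(v, label=l) for v, l in ((1.0, Q), (0.5, C), (0.25, Q))]
        pipe = oracle_pipeline()
        assert (
            accumulate(a + b, **pipe).ccmea
            == accumulate(a, **pipe).ccmea + accumulate(b, **pipe).ccmea
        )

    def test_monotonicity_in_stream_growth(self):
        pipe = oracle_pipeline()
        base = [synthetic_item(0.5)] * 5
        with_q = base + [synthetic_item(0.25)]
        with_u = base + [synthetic_item(0.9, label=B)]
        c0 = accumulate(base, **pipe).ccmea
        assert accumulate(with_q, **pipe).ccmea >= c0
        assert accumulate(with_u, **pipe).ccmea == c0

    def test_bound_by_qualified_count(self, small_spec):
        frames = generate_procedure(30, [(Q, 20), (B, 10)], small_spec)
        record = accumulate(frames, **oracle_pipeline())
        assert 0.0 <= record.ccmea <= record.n_qualified == 20

    def test_oracle_equivalence_on_rendered_procedure(self, small_spec):
        frames = generate_procedure(24, [(Q, 10), (C, 4), (Q, 6), (V, 4)], small_spec)
        expected = sum(pf.cmea_truth for pf in frames if pf.label is Q)
        assert accumulate(frames, **oracle_pipeline()).ccmea == expected

    def test_empty_stream_record(self):
        record = accumulate([])
        assert record.ccmea == 0.0
        assert record.qualified_flag is False
        assert record.n_frames_total == 0

    def test_counts_sum_and_json_roundtrip(self, small_spec):
        import json

        frames = generate_procedure(12, [(Q, 6), (C, 3), (V, 3)], small_spec)
        record = accumulate(frames, **oracle_pipeline())
        assert record.n_qualified + record.n_chromo + record.n_other_unqualified == 12
        payload = json.loads(record.to_json())
        assert payload["ccmea"] == record.ccmea
        assert payload["sampling_rate"] == record.sampling_rate

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            accumulate([], threshold=-1)


class TestScoring:
    @pytest.fixture()
    def frame_dir(self, tmp_path, small_spec):
        import imageio.v3 as iio

        frames = generate_procedure(20, [(Q, 20)], small_spec.replace(artifact_budget={}))
        for pf in frames:
            iio.imwrite(
                tmp_path / f"frame_{pf.frame.index:04d}.png",
                (pf.frame.image * 255).astype(np.uint8),
            )
        return tmp_path

    def test_directory_of_phantoms(self, frame_dir):
        record, log = score_directory(frame_dir, threshold=5.0)
        assert record.n_frames_total == 20
        assert len(log) == 20
        assert list(log.columns) == ["frame_index", "frame_class", "cmea"]

    def test_rescoring_is_deterministic(self, frame_dir):
        r1, log1 = score_directory(frame_dir)
        r2, log2 = score_directory(frame_dir)
        assert r1.ccmea == r2.ccmea
        assert log1.to_csv(index=False) == log2.to_csv(index=False)

    def test_temporal_downsampling_halves_ccmea(self):
        """Constant-CMEA stream: scoring every other frame halves the sum."""
        items = [synthetic_item(0.6) for _ in range(40)]
        pipe = oracle_pipeline()
        full = accumulate(items, **pipe).ccmea
        half = accumulate(items[::2], **pipe).ccmea
        assert abs(full - 2 * half) <= 0.6  # within one frame's contribution

    def test_frame_window(self, frame_dir):
        record, _ = score_directory(frame_dir, start=5, end=15)
        assert record.n_frames_total == 10

    def test_unreadable_input_names_file(self, tmp_path):
        bogus = tmp_path / "not_a_video.mp4"
        bogus.write_bytes(b"this is not a container")
        with pytest.raises(Exception, match="not_a_video"):
            score_video(bogus)

    def test_missing_input_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            score_video(tmp_path / "absent.mp4")

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            score_directory(tmp_path)

    def test_score_frames_log_matches_record(self, small_spec):
        frames = generate_procedure(10, [(Q, 7), (B, 3)], small_spec)
        record, log = score_frames(frames, **oracle_pipeline())
        assert len(log) == 10
        assert log.cmea.dropna().sum() == record.ccmea
        assert (log.frame_class == "blurred").sum() == 3
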