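import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilescan import (
    NormalizationAnchors,
    combine_replicates,
    compute_anchors,
    crispr_score,
    default_pseudofreq,
    normalize,
)
from tilescan.tiling_score import ScreenQualityError


def _series(vals, idx=None):
    return pd.Series(vals, index=idx or [f"g{i}" for i in range(len(vals))], dtype=float)


class TestCrisprScore:
    def test_unchanged_frequency_scores_zero(self):
        f = _series([0.1, 0.2, 0.7])
        assert np.allclose(crispr_score(f, f, 1e-9), 0.0)

    def test_tenfold_dropout_scores_minus_one(self):
        cs = crispr_score(_series([1e-3]), _series([1e-4]), pseudofreq=1e-12)
        assert cs.iloc[0] == pytest.approx(-1.0, abs=1e-6)

    def test_pseudofrequency_enters_both_numerator_and_denominator(self):
        cs = crispr_score(_series([0.02]), _series([0.005]), pseudofreq=1e-6)
        assert cs.iloc[0] == pytest.approx(np.log10(0.005001 / 0.020001), abs=1e-12)
        assert cs.iloc[0] == pytest.approx(-0.602, abs=5e-4)

    def test_mismatched_guide_sets_rejected(self):
        with pytest.raises(ValueError, match="guide sets"):
            crispr_score(_series([0.1]), _series([0.1], idx=["other"]), 1e-6)

    @given(
        st.lists(st.tuples(st.floats(1e-6, 1.0), st.floats(1e-6, 1.0)), min_size=1, max_size=20),
        st.floats(1e-9, 1e-2),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_antisymmetric_under_timepoint_swap(self, pairs, pf):
        f0 = _series([a for a, _ in pairs])
        f1 = _series([b for _, b in pairs])
        fwd = crispr_score(f0, f1, pf)
        rev = crispr_score(f1, f0, pf)
        assert np.allclose(fwd + rev, 0.0, atol=1e-12)

    def test_moderation_shrinks_low_count_guides_toward_zero(self):
        f0, f1 = _series([0.01, 0.01]), _series([0.001, 0.001])
        counts = pd.DataFrame({"c0": [1000, 2], "c30": [100, 1]}, index=f0.index)
        raw = crispr_score(f0, f1, 1e-6)
        mod = crispr_score(f0, f1, 1e-6, moderate_counts=counts, moderation_k=10.0)
        assert mod.iloc[0] == pytest.approx(raw.iloc[0] * 100 / 110)
        assert abs(mod.iloc[1]) < abs(mod.iloc[0])


class TestCombineReplicates:
    def test_single_replicate_unchanged(self):
        t = _series([0.5, -0.5])
        mean, spread = combine_replicates([t])
        assert mean.equals(t.rename("score"))
        assert (spread == 0).all()

    @pytest.mark.parametrize(
        "reps, expected", [([-0.4, -0.6], -0.5), ([0.1, -0.1, 0.3], 0.1)]
    )
    def test_unweighted_mean(self, reps, expected):
        tracks = [_series([v]) for v in reps]
        mean, spread = combine_replicates(tracks)
        assert mean.iloc[0] == pytest.approx(expected)
        assert spread.iloc[0] == pytest.approx(max(reps) - min(reps))

    def test_inconsistent_guide_sets_rejected(self):
        with pytest.raises(ValueError, match="guide sets"):
            combine_replicates([_series([1.0]), _series([1.0], idx=["x"])])


def _score_frame(neg, kill, tiling=()):
    rows = (
        [("negative_control", v) for v in neg]
        + [("killing_control", v) for v in kill]
        + [("tiling", v) for v in tiling]
    )
    return pd.DataFrame(
        {"guide_id": [f"g{i}" for i in range(len(rows))],
         "category": [c for c, _ in rows],
         "score": [v for _, v in rows]}
    )


class TestAnchors:
    @pytest.mark.parametrize(
        "neg, kill, expected",
        [
            ([0.1, -0.1], [-1.0], (0.0, -1.0)),
            ([0.2, 0.0, 0.1], [-0.8, -1.2], (0.1, -1.0)),  # even kill count -> midpoint
        ],
    )
    def test_medians_by_category(self, neg, kill, expected):
        anchors = compute_anchors(_score_frame(neg, kill))
        assert (anchors.m_neg, anchors.m_kill) == pytest.approx(expected)

    def test_killing_controls_must_drop_below_negatives(self):
        with pytest.raises(ScreenQualityError, match="did not drop"):
            compute_anchors(_score_frame(neg=[-0.5], kill=[-0.2]))

    def test_missing_control_class_rejected(self):
        with pytest.raises(ScreenQualityError, match="negative"):
            compute_anchors(_score_frame(neg=[], kill=[-1.0]))


class TestNormalize:
    def test_anchor_points_map_to_definitional_values(self):
        a = NormalizationAnchors(0.1, -0.9)
        assert normalize(0.1, a) == pytest.approx(0.0)
        assert normalize(-0.9, a) == pytest.approx(-1.0)
        assert normalize(-0.4, a) == pytest.approx(-0.5)

    @given(
        st.floats(-0.5, 0.5), st.floats(0.2, 3.0),
        st.lists(st.floats(-5, 5), min_size=2, max_size=10),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_affine_and_order_preserving(self, m_neg, span, values):
        a = NormalizationAnchors(m_neg, m_neg - span)
        out = normalize(np.array(values), a)
        # monotone: sorted inputs give (weakly, under fp rounding) sorted outputs
        assert (np.diff(out[np.argsort(values, kind="stable")]) >= -1e-15).all()
        # affine: respects midpoints
        mid = normalize((values[0] + values[1]) / 2, a)
        assert mid == pytest.approx((out[0] + out[1]) / 2, abs=1e-9)

    def test_control_medians_normalize_to_exact_anchors(self, rng):
        frame = _score_frame(
            neg=rng.normal(0, 0.1, 11).tolist(),
            kill=rng.normal(-1, 0.1, 7).tolist(),
            tiling=rng.normal(-0.3, 0.4, 50).tolist(),
        )
        anchors = compute_anchors(frame)
        norm = normalize(frame["score"], anchors)
        assert norm[frame["category"] == "negative_control"].median() == pytest.approx(0.0, abs=1e-12)
        assert norm[frame["category"] == "killing_control"].median() == pytest.approx(-1.0, abs=1e-12)


def test_default_pseudofreq_is_half_read_of_shallowest_sample():
    counts = pd.DataFrame({"a": [5, 5], "b": [2, 2]})
    assert default_pseudofreq(counts) == pytest.approx(0.5 / 4)
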