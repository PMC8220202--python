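"""FPKM normalization, signed fold changes, and the breakpoint-window screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fishea.expression import (
    DEFAULT_WINDOWS,
    RegionWindow,
    candidate_genes,
    chromosome_landscape,
    extract_window,
    log_normalize,
    median_adjust,
    ratio_to_signed,
    signed_fold_change,
)
from fishea.synthetic import EffectSpec, gen_expression_dataset


def _matrix(values, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])], columns=samples)


class TestMedianAdjust:
    def test_direct_median_division(self):
        m = _matrix([[2.0], [4.0], [8.0]])
        out = median_adjust(m)
        assert out["S0"].tolist() == [0.5, 1.0, 2.0]

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.lognormal(1.0, 1.0, size=(51, 3)))
        once = median_adjust(m)
        twice = median_adjust(once)
        pd.testing.assert_frame_equal(once, twice)

    @settings(max_examples=25, derandomize=True)
    @given(
        arrays(
            float,
            st.tuples(st.integers(3, 40), st.integers(1, 4)),
            elements=st.floats(0.01, 1e4),
        )
    )
    def test_post_median_is_one(self, values):
        out = median_adjust(_matrix(values))
        assert np.allclose(out.median(axis=0), 1.0, atol=1e-12)

    def test_gene_ratios_between_samples_preserved(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng.lognormal(0.0, 1.0, size=(31, 2)))
        out = median_adjust(m)
        ratio_before = m["S0"] / m["S1"]
        scale = (out["S0"] / out["S1"]) / ratio_before
        assert np.allclose(scale, scale.iloc[0])

    def test_zero_median_errors_unless_fallback(self):
        m = _matrix([[0.0], [0.0], [3.0]])
        with pytest.raises(ValueError, match="median"):
            median_adjust(m)
        out = median_adjust(m, nonzero_median=True)
        assert out["S0"].tolist() == [0.0, 0.0, 1.0]

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            median_adjust(_matrix([[1.0], [-0.5], [2.0]]))


class TestLogNormalize:
    def test_fixed_points(self):
        m = _matrix([[0.0], [1.0], [2.0]])
        out = log_normalize(m, already_adjusted=True)
        assert out["S0"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["S0"].iloc[1] == pytest.approx(2.0, abs=1e-12)

    def test_formula_at_99(self):
        out = log_normalize(_matrix([[99.0], [1.0], [0.5]]), already_adjusted=True)
        assert out["S0"].iloc[0] == pytest.approx(np.log10(9802), abs=1e-12)

    def test_strictly_increasing_and_zero_iff_silent(self):
        x = np.sort(np.concatenate([[0.0], np.logspace(-4, 3, 41)]))
        out = log_normalize(_matrix(x[:, None]), already_adjusted=True)["S0"].to_numpy()
        assert (np.diff(out) > 0).all()
        assert out[0] == 0.0 and (out[1:] > 0).all()

    def test_applies_median_adjustment_by_default(self):
        m = _matrix([[2.0], [4.0], [8.0]])
        out = log_normalize(m)
        # the median gene lands exactly on the second fixed point
        assert out["S0"].iloc[1] == pytest.approx(2.0, abs=1e-12)


class TestSignedFoldChange:
    def test_no_change_is_plus_one(self):
        for v in (0.0, 0.5, 1.0, 42.0):
            assert signed_fold_change(v, v) == pytest.approx(1.0)

    def test_silent_denominator_saturates_at_hundredfold(self):
        assert signed_fold_change(1.0, 0.0) == pytest.approx(100.0)
        assert signed_fold_change(0.0, 1.0) == pytest.approx(-100.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0, 1e3), st.floats(0, 1e3))
    def test_antisymmetry(self, a, b):
        fwd = signed_fold_change(a, b)
        rev = signed_fold_change(b, a)
        assert abs(fwd) >= 1 and abs(rev) >= 1
        # +r maps to -r (and +1 maps to +1, since -1 and +1 are the same ratio)
        assert np.isclose(abs(fwd), abs(rev), rtol=1e-9)
        if abs(fwd) > 1:
            assert np.sign(fwd) == -np.sign(rev)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0, 1e3), st.floats(0, 1e3))
    def test_shifted_mode_equals_normalized_expression_difference(self, a, b):
        delta = np.log10(1 + 99 * a) - np.log10(1 + 99 * b)
        expected = ratio_to_signed(10.0 ** delta)
        assert signed_fold_change(a, b, mode="shifted") == pytest.approx(expected)

    def test_raw_mode_uses_pseudocount(self):
        assert signed_fold_change(1.0, 0.0, mode="raw", pseudocount=0.01) == pytest.approx(101.0)
        assert signed_fold_change(4.0, 2.0, mode="raw", pseudocount=0.0) == pytest.approx(2.0)


class TestExtractWindow:
    def test_shipped_2p22_window_returns_catalog_in_coordinate_order(self, annotation):
        genes = extract_window(annotation, DEFAULT_WINDOWS["2p22"])
        assert len(genes) == 14
        assert genes["gene_id"].iloc[0] == "FNDC4"
        assert genes["gene_id"].iloc[-1] == "RASGRP3"
        assert genes["start"].is_monotonic_increasing

    def test_gene_outside_window_excluded(self, annotation):
        w = RegionWindow("w", "2", 1_000, 2_000)
        assert extract_window(annotation, w).empty

    def test_one_bp_edge_overlap_included(self):
        ann = pd.DataFrame(
            {
                "gene_id": ["left_touch", "right_touch", "inside", "out_left", "out_right"],
                "chrom": ["5"] * 5,
                "start": [50, 200, 120, 10, 201],
                "end": [100, 300, 150, 99, 400],
            }
        )
        w = RegionWindow("w", "5", 100, 200)
        got = extract_window(ann, w)["gene_id"].tolist()
        assert got == ["left_touch", "inside", "right_touch"]


class TestCandidateGenes:
    def _dataset(self, effects, sd, seed=0, n_genes=300):
        fpkm, ann, _ = gen_expression_dataset(
            n_genes, effects=effects, background_sd=sd, seed=seed
        )
        return log_normalize(fpkm), ann

    def test_noiseless_planted_gene_passes_and_background_fails(self):
        norm, ann = self._dataset([EffectSpec("HIT", 4.0, "2p22")], sd=0.0)
        out = candidate_genes(norm, ann, contrast=("BEC40W", "BEC20W"))
        assert out.set_index("gene_id").loc["HIT", "passes"]
        assert out["passes"].sum() == 1  # background windows contribute nothing

    def test_subthreshold_gene_reported_unfiltered_but_fails(self):
        norm, ann = self._dataset([EffectSpec("WEAK", 1.5, "10q22")], sd=0.0)
        out = candidate_genes(norm, ann, contrast=("BEC40W", "BEC20W"))
        row = out.set_index("gene_id").loc["WEAK"]
        assert not row["passes"]
        assert row["fc"] == pytest.approx(1.5, rel=0.01)

    def test_sign_matches_planted_direction_in_noiseless_limit(self):
        effects = [EffectSpec("UP", 6.0, "2p22"), EffectSpec("DOWN", -6.0, "16q22")]
        norm, ann = self._dataset(effects, sd=0.0)
        out = candidate_genes(norm, ann, contrast=("BEC40W", "BEC20W")).set_index("gene_id")
        assert out.loc["UP", "fc"] > 0
        assert out.loc["DOWN", "fc"] < 0

    def test_raising_threshold_never_adds_passing_genes(self):
        effects = [
            EffectSpec("A", 3.0, "2p22"),
            EffectSpec("B", -5.0, "10q22"),
            EffectSpec("C", 10.0, "16q22"),
        ]
        norm, ann = self._dataset(effects, sd=0.2, seed=5)
        passing = []
        for thr in (1.5, 2.0, 3.0, 6.0, 20.0):
            out = candidate_genes(norm, ann, contrast=("BEC40W", "BEC20W"), fc_threshold=thr)
            passing.append(set(out.loc[out["passes"], "gene_id"]))
        for small, big in zip(passing[1:], passing):
            assert small <= big

    def test_unknown_contrast_sample_raises(self):
        norm, ann = self._dataset([], sd=0.1)
        with pytest.raises(KeyError):
            candidate_genes(norm, ann, contrast=("BEC40W", "NOPE"))

    def test_permutation_null_agrees_with_background_null_on_symmetric_noise(self):
        norm, ann = self._dataset([EffectSpec("HIT", 8.0, "2p22")], sd=0.2, seed=3)
        bg = candidate_genes(norm, ann, contrast=("BEC40W", "BEC20W"))
        perm = candidate_genes(
            norm, ann, contrast=("BEC40W", "BEC20W"), null="permutation",
            rng=np.random.default_rng(0),
        )
        assert bool(bg.set_index("gene_id").loc["HIT", "passes"])
        assert bool(perm.set_index("gene_id").loc["HIT", "passes"])


class TestLandscape:
    def test_track_length_equals_gene_count_on_chromosome(self, annotation):
        rng = np.random.default_rng(2)
        fpkm = pd.DataFrame(
            rng.lognormal(1.0, 0.5, size=(len(annotation), 2)),
            index=annotation["gene_id"],
            columns=["BEC20W", "BEC40W"],
        )
        norm = log_normalize(fpkm)
        for chrom in ("2", "10", "16"):
            track = chromosome_landscape(norm, annotation, chrom, ("BEC40W", "BEC20W"))
            assert len(track) == (annotation["chrom"] == chrom).sum()
            assert track["position"].is_monotonic_increasing

    def test_track_values_recompute_from_normalized_difference(self, annotation):
        rng = np.random.default_rng(3)
        fpkm = pd.DataFrame(
            rng.lognormal(1.0, 0.5, size=(len(annotation), 2)),
            index=annotation["gene_id"],
            columns=["BEC20W", "BEC40W"],
        )
        norm = log_normalize(fpkm)
        track = chromosome_landscape(norm, annotation, "16", ("BEC40W", "BEC20W"))
        for gid, val in zip(track["gene_id"], track["log10fc"]):
            assert val == pytest.approx(norm.loc[gid, "BEC40W"] - norm.loc[gid, "BEC20W"])

    def test_empty_chromosome_gives_empty_track(self, annotation):
        fpkm = pd.DataFrame(
            1.0, index=annotation["gene_id"], columns=["BEC20W", "BEC40W"]
        )
        track = chromosome_landscape(log_normalize(fpkm, nonzero_median=True), annotation, "21", ("BEC40W", "BEC20W"))
        assert track.empty
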