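"""Correlation/regression battery: GC computation, depth normalization,
Pearson oracle agreement, stratification and sign recovery on simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from parsbias import (
    DEFAULT_STRATA,
    GcStratum,
    SimConfig,
    StartCountTrack,
    compute_profile,
    depth_vs_gc,
    depth_vs_pars,
    gene_gc,
    normalized_depths,
    pearson,
    pctds_vs_gc,
    per_strain_regression,
    simulate_dataset,
)
from _oracles import oracle_pearson


class TestGeneGc:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GCGC", 1.0), ("ATAT", 0.0), ("ATGC", 0.5), ("ATGN", 1 / 3), ("atgc", 0.5)],
    )
    def test_fraction_over_unambiguous_bases(self, seq, expected):
        assert gene_gc(seq) == pytest.approx(expected)

    def test_all_ambiguous_is_an_error(self):
        with pytest.raises(ValueError, match="unambiguous"):
            gene_gc("NNNN")


class TestNormalizedDepth:
    def _track(self, tid, control):
        n = len(control)
        return StartCountTrack(tid, np.zeros(n, int), np.zeros(n, int),
                               np.asarray(control))

    def test_single_gene_self_normalizes_to_one(self):
        d = normalized_depths([self._track("g", [5, 5, 5, 5])])
        assert d["g"] == pytest.approx(1.0)

    def test_three_to_one_ratio(self):
        tracks = [self._track("a", [3] * 10), self._track("b", [1] * 10)]
        d = normalized_depths(tracks)
        assert d["a"] == pytest.approx(1.5)
        assert d["b"] == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        counts = [rng.poisson(5, 30) for _ in range(4)]
        d1 = normalized_depths([self._track(f"g{i}", c) for i, c in enumerate(counts)])
        d2 = normalized_depths(
            [self._track(f"g{i}", c * 7) for i, c in enumerate(counts)]
        )
        for k in d1:
            assert d1[k] == pytest.approx(d2[k])

    def test_length_weighted_mean_is_one(self, rng):
        tracks = [
            self._track(f"g{i}", rng.poisson(5, int(rng.integers(10, 50))))
            for i in range(6)
        ]
        d = normalized_depths(tracks)
        total = sum(d[t.transcript_id] * t.length for t in tracks)
        assert total / sum(t.length for t in tracks) == pytest.approx(1.0)

    def test_zero_total_counts_is_an_error(self):
        with pytest.raises(ValueError, match="zero total"):
            normalized_depths([self._track("g", [0, 0, 0])])


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_matches_covariance_oracle_to_1e12(self, rng):
        for _ in range(30):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            res = pearson(x, y)
            r_o, p_o = oracle_pearson(list(x), list(y))
            assert res.r == pytest.approx(r_o, abs=1e-12)
            assert res.p_value == pytest.approx(p_o, rel=1e-6)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_few_points_is_an_error(self):
        with pytest.raises(ValueError, match="3"):
            pearson([1, 2], [3, 4])


class TestDepthVsPars:
    def test_negative_association_under_structure_penalty(self):
        cfg = SimConfig(target_gc=0.5, n_transcripts=10, seed=31)
        truth, tracks = simulate_dataset(cfg)
        rs = []
        for track in tracks:
            profile = compute_profile(track)
            rs.append(depth_vs_pars(profile, track).r)
        # the control library is depressed at paired (high-score) positions
        assert np.mean(rs) < 0
        assert sum(r < 0 for r in rs) >= 8

    def test_permutation_invariance(self, rng):
        cfg = SimConfig(target_gc=0.5, n_transcripts=1, seed=32)
        _, (track,) = simulate_dataset(cfg)
        profile = compute_profile(track)
        r1 = depth_vs_pars(profile, track).r
        perm = rng.permutation(track.length)
        track2 = StartCountTrack(
            "g", track.counts_v1[perm], track.counts_s1[perm],
            track.counts_control[perm],
        )
        profile2 = compute_profile(track2)
        assert depth_vs_pars(profile2, track2).r == pytest.approx(r1)

    def test_constant_scores_raise(self):
        from parsbias import ParsProfile

        n = 10
        profile = ParsProfile("g", np.full(n, 3.0), np.ones(n, np.int8),
                              np.ones(n, np.int8), 1.0, True)
        track = StartCountTrack("g", np.ones(n, int) * 8, np.ones(n, int),
                                np.arange(n))
        with pytest.raises(ValueError, match="variance"):
            depth_vs_pars(profile, track)


def _summaries(gc, depth, pct_ds=None, strain="s1", retained=True):
    n = len(gc)
    return pd.DataFrame(
        {
            "transcript_id": [f"g{i}" for i in range(n)],
            "strain_id": strain,
            "gc_fraction": gc,
            "mean_depth_norm": depth,
            "pct_ds": pct_ds if pct_ds is not None else [0.5] * n,
            "n_positions": 100,
            "retained": retained,
        }
    )


class TestDepthVsGc:
    def test_boundary_gene_at_060_in_medium_not_high(self, rng):
        gc = [0.2, 0.3, 0.45, 0.5, 0.55, 0.60]
        df = _summaries(gc, rng.normal(1, 0.1, len(gc)))
        results = {c.stratum: c for c in depth_vs_gc(df)}
        assert results["medium"].n == 4  # 0.45, 0.5, 0.55, 0.60
        assert results["high"].n == 0 and not results["high"].computable

    def test_small_stratum_flagged_not_computable(self, rng):
        df = _summaries([0.3, 0.32, 0.35, 0.38], rng.normal(1, 0.1, 4))
        results = {c.stratum: c for c in depth_vs_gc(df)}
        assert not results["high"].computable
        assert results["high"].note != ""
        assert results["pooled"].computable

    def test_gene_order_invariance(self, rng):
        gc = rng.uniform(0.2, 0.8, 30)
        depth = rng.normal(1, 0.2, 30)
        df = _summaries(list(gc), list(depth))
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        r1 = {c.stratum: c.r for c in depth_vs_gc(df)}
        r2 = {c.stratum: c.r for c in depth_vs_gc(shuffled)}
        for k in r1:
            assert r1[k] == pytest.approx(r2[k], nan_ok=True)

    def test_overlapping_default_strata_kept_verbatim(self):
        labels = {(s.label, s.lo, s.hi) for s in DEFAULT_STRATA}
        assert ("low", -np.inf, 0.40) in labels
        assert ("medium", 0.35, 0.60) in labels
        assert ("high", 0.60, np.inf) in labels
        # a gene at 0.38 falls in both low and medium
        assert DEFAULT_STRATA[0].contains(0.38) and DEFAULT_STRATA[1].contains(0.38)


class TestPerStrainRegression:
    def test_exact_linear_depth(self):
        gc = np.linspace(0.2, 0.8, 10)
        df = _summaries(list(gc), list(2.0 - 1.5 * gc))
        fit = per_strain_regression(df).iloc[0]
        assert fit["slope"] == pytest.approx(-1.5)
        assert fit["intercept"] == pytest.approx(2.0)
        assert fit["p_value"] < 1e-12

    def test_slope_equals_r_times_sd_ratio(self, rng):
        gc = rng.uniform(0.2, 0.8, 25)
        depth = rng.normal(1, 0.3, 25)
        df = _summaries(list(gc), list(depth))
        fit = per_strain_regression(df).iloc[0]
        r = pearson(gc, depth).r
        assert fit["slope"] == pytest.approx(r * np.std(depth) / np.std(gc))

    def test_constant_gc_is_degenerate(self):
        df = _summaries([0.5] * 5, [1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="constant GC"):
            per_strain_regression(df)

    def test_slope_magnitude_grows_with_strain_gc(self, three_strain_study):
        _, results = three_strain_study
        reg = results.strain_regressions.set_index("strain_id")
        assert abs(reg.loc["highgc", "slope"]) > abs(reg.loc["midgc", "slope"])
        assert reg.loc["highgc", "p_value"] < 0.001


class TestPctDsVsGc:
    def test_positive_under_gc_structure_coupling(self, three_strain_study):
        _, results = three_strain_study
        assert results.pctds_gc.r > 0
        assert results.pctds_gc.p_value < 1e-6

    def test_identical_pct_ds_is_an_error(self):
        df = _summaries([0.3, 0.5, 0.7], [1.0, 1.1, 0.9], pct_ds=[0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="variance"):
            pctds_vs_gc(df)

    def test_null_coupling_gives_uniform_pvalues(self):
        # no GC-structure link and no depth penalties: the pooled depth-GC
        # p-value should reject at roughly the nominal rate
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            cfg = SimConfig(target_gc=0.5, struct_gc_slope=0.0, gamma_gc=0.0,
                            gamma_struct=0.0, n_transcripts=12,
                            length_range=(60, 120), gc_window=31, seed=seed)
            truth, tracks = simulate_dataset(cfg)
            gc = [gene_gc(t.sequence) for t in truth]
            depth = normalized_depths(tracks)
            df = _summaries(gc, [depth[t.transcript_id] for t in tracks])
            try:
                res = pearson(df["gc_fraction"], df["mean_depth_norm"])
            except ValueError:
                continue
            if res.p_value < 0.05:
                rejections += 1
        # binomial(200, 0.05): 3 sd band around 10
        assert 1 <= rejections <= 20


class TestHeadlineDirections:
    def test_three_strain_study_reproduces_result_directions(self, three_strain_study):
        truths, results = three_strain_study
        by_stratum = {c.stratum: c for c in results.depth_gc}
        # high-GC stratum: strong inverse depth-GC relation
        assert by_stratum["high"].computable and by_stratum["high"].r < 0
        # structure prevalence rises with GC
        assert results.pctds_gc.r > 0
        # structured positions have fewer control read starts
        assert results.pooled_logit.converged and results.pooled_logit.beta1 < 0
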