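"""Scoring stages against closed forms, bootstrap and spreadsheet oracles."""

import numpy as np
import pandas as pd
import pytest

from mavemap.scoring import (ScoringConfig, TileSeqScorer, _lad_fit,
                             apply_filters, combine_replicates,
                             compute_frequencies, enrichment_scores,
                             regularize_errors, rescale_scores,
                             score_pipeline)

D = 1_000_000

# toy single-tile screen: 2 nonsense + 2 synonymous anchors + 6 missense,
# two replicates of each condition, depth 1e6
TOY_VARIANTS = {
    "p.Ala2Ter": "nonsense", "p.Gly3Ter": "nonsense",
    "p.Leu4Leu": "synonymous", "p.Ser5Ser": "synonymous",
    "p.Gly6Arg": "missense", "p.Val7Ala": "missense",
    "p.Thr8Met": "missense", "p.Lys9Glu": "missense",
    "p.Ile10Asn": "missense", "p.Pro11Ser": "missense",
}
TOY_COUNTS = {
    #              pre1   pre2   post1  post2  wt1  wt2
    "p.Ala2Ter":  (400,   380,   12,    15,    2,   4),
    "p.Gly3Ter":  (350,   500,   10,    18,    0,   2),
    "p.Leu4Leu":  (300,   280,   310,   260,   3,   1),
    "p.Ser5Ser":  (500,   520,   480,   560,   2,   2),
    "p.Gly6Arg":  (250,   240,   20,    25,    1,   3),
    "p.Val7Ala":  (600,   650,   590,   640,   4,   2),
    "p.Thr8Met":  (420,   400,   200,   210,   2,   0),
    "p.Lys9Glu":  (330,   310,   160,   170,   1,   1),
    "p.Ile10Asn": (9,     400,   5,     200,   0,   0),   # rep1 below min_count
    "p.Pro11Ser": (280,   300,   0,     3,     2,   2),   # post depleted to 0
}


def toy_bundle():
    rows = []
    for v, (p1, p2, q1, q2, w1, w2) in TOY_COUNTS.items():
        rows += [
            (1, "pre", 1, v, p1, D), (1, "pre", 2, v, p2, D),
            (1, "post", 1, v, q1, D), (1, "post", 2, v, q2, D),
            (1, "wt_control", 1, v, w1, D), (1, "wt_control", 2, v, w2, D),
        ]
    return pd.DataFrame(rows, columns=["tile", "condition", "replicate",
                                       "variant", "count", "depth"])


TOY_CFG = ScoringConfig(min_anchors=2, min_fit_variants=10_000)  # no shrinkage


def spreadsheet_scores():
    """Independent flat recomputation of every stage on the toy bundle."""
    wt_freqs = {v: [c[4] / D * 1e6, c[5] / D * 1e6]
                for v, c in TOY_COUNTS.items()}
    wt_mean = {v: np.mean(f) for v, f in wt_freqs.items()}
    pooled_wt = sorted(f for fs in wt_freqs.values() for f in fs)
    thr = float(np.percentile(pooled_wt, 90))

    per_rep = {1: {}, 2: {}}
    for rep in (1, 2):
        for v, c in TOY_COUNTS.items():
            pre_c, post_c = c[rep - 1], c[rep + 1]
            f_pre, f_post = pre_c / D * 1e6, post_c / D * 1e6
            excluded = pre_c < 10 or f_pre <= thr
            fw = wt_mean[v]
            fpc, fqc = f_pre - fw, f_post - fw
            floored = fqc <= 0
            if floored:
                fqc = 0.5 / D * 1e6
            unmeasurable = excluded or fpc <= 0
            if unmeasurable:
                per_rep[rep][v] = None
                continue
            var_pre = f_pre * 1e6 / D
            var_post = f_post * 1e6 / D
            var_wt = fw * 1e6 / D / 2  # two pooled WT replicates
            var_post_c = max(var_post + var_wt, (0.5 / D * 1e6) * 1e6 / D)
            logphi = np.log2(fqc / fpc)
            var_log = (1 / np.log(2)) ** 2 * (
                var_post_c / fqc ** 2 + (var_pre + var_wt) / fpc ** 2)
            per_rep[rep][v] = (logphi, np.sqrt(var_log))

    combined = {}
    rep_scores = {1: {}, 2: {}}
    for rep in (1, 2):
        vals = {v: s for v, s in per_rep[rep].items() if s is not None}
        non = np.median([vals[v][0] for v in vals
                         if TOY_VARIANTS[v] == "nonsense"])
        syn = np.median([vals[v][0] for v in vals
                         if TOY_VARIANTS[v] == "synonymous"])
        scale = syn - non
        assert scale > 0
        for v, (lp, se) in vals.items():
            rep_scores[rep][v] = ((lp - non) / scale, se / scale)
    for v in TOY_VARIANTS:
        reps = [rep_scores[r][v] for r in (1, 2) if v in rep_scores[r]]
        if not reps:
            continue
        if len(reps) == 1:
            combined[v] = reps[0]
        else:
            w = np.array([1 / se ** 2 for _, se in reps])
            s = np.array([s for s, _ in reps])
            combined[v] = (float((w * s).sum() / w.sum()),
                           float(np.sqrt(1 / w.sum())))
    return rep_scores, combined


class TestFrequencies:
    def test_ppm_conversion(self):
        freqs = compute_frequencies(toy_bundle())
        row = freqs[(freqs["variant"] == "p.Ala2Ter") &
                    (freqs["condition"] == "pre") & (freqs["replicate"] == 1)]
        assert row["freq"].iloc[0] == 400 / D * 1e6
        zero = freqs[freqs["count"] == 0]
        assert (zero["freq"] == 0).all()

    def test_tile_conservation(self):
        freqs = compute_frequencies(toy_bundle())
        sums = freqs.groupby(["tile", "condition", "replicate"])["freq"].sum()
        assert (sums <= 1e6).all()

    def test_zero_depth_names_cell(self):
        bad = toy_bundle()
        bad.loc[0, "depth"] = 0
        with pytest.raises(ValueError, match="tile=1"):
            compute_frequencies(bad)


class TestFilters:
    def test_low_count_excluded(self):
        filt = apply_filters(compute_frequencies(toy_bundle()), TOY_CFG)
        row = filt[(filt["variant"] == "p.Ile10Asn") & (filt["replicate"] == 1)]
        assert row["excluded"].iloc[0]
        row2 = filt[(filt["variant"] == "p.Ile10Asn") & (filt["replicate"] == 2)]
        assert not row2["excluded"].iloc[0]

    def test_well_measured_needs_min_ppm(self):
        filt = apply_filters(compute_frequencies(toy_bundle()), TOY_CFG)
        kept = filt[~filt["excluded"]]
        assert (kept["freq_pre"] >= 10).all()
        assert kept["well_measured"].all()

    def test_all_zero_wt_disables_percentile_rule(self):
        bundle = toy_bundle()
        bundle.loc[bundle["condition"] == "wt_control", "count"] = 0
        filt = apply_filters(compute_frequencies(bundle), TOY_CFG)
        excl = filt[filt["excluded"]]
        assert (excl["count_pre"] < 10).all()

    def test_monotone_in_min_count(self):
        freqs = compute_frequencies(toy_bundle())
        kept = {}
        for mc in (5, 10, 300):
            cfg = ScoringConfig(min_count=mc, min_anchors=2)
            filt = apply_filters(freqs, cfg)
            kept[mc] = set(map(tuple, filt.loc[~filt["excluded"],
                                               ["variant", "replicate"]].values))
        assert kept[300] <= kept[10] <= kept[5]


class TestEnrichment:
    def _enriched(self):
        filt = apply_filters(compute_frequencies(toy_bundle()), TOY_CFG)
        return enrichment_scores(filt)

    def test_equal_frequencies_zero_log_ratio(self):
        df = pd.DataFrame({
            "tile": [1], "variant": ["p.Ala2Val"], "replicate": [1],
            "freq_pre": [100.0], "freq_post": [100.0], "wt_freq": [0.0],
            "count_pre": [100], "count_post": [100],
            "depth_pre": [D], "depth_post": [D], "wt_depth": [D], "wt_n": [1],
            "excluded": [False], "well_measured": [True],
        })
        out = enrichment_scores(df)
        assert out["log_phi"].iloc[0] == 0.0

    def test_wt_equal_pre_unmeasurable(self):
        df = pd.DataFrame({
            "tile": [1], "variant": ["p.Ala2Val"], "replicate": [1],
            "freq_pre": [50.0], "freq_post": [80.0], "wt_freq": [50.0],
            "count_pre": [50], "count_post": [80],
            "depth_pre": [D], "depth_post": [D], "wt_depth": [D], "wt_n": [1],
            "excluded": [False], "well_measured": [True],
        })
        out = enrichment_scores(df)
        assert out["unmeasurable"].iloc[0]
        assert np.isnan(out["log_phi"].iloc[0])

    def test_post_depletion_floored_not_dropped(self):
        out = self._enriched()
        row = out[(out["variant"] == "p.Pro11Ser") & (out["replicate"] == 1)]
        assert row["floored"].iloc[0]
        assert not row["unmeasurable"].iloc[0]
        assert np.isfinite(row["log_phi"].iloc[0])

    def test_delta_method_matches_poisson_bootstrap(self):
        """10^5-draw parametric bootstrap of log2((post-wt)/(pre-wt))."""
        f_pre, f_post, f_wt = 200.0, 50.0, 10.0
        df = pd.DataFrame({
            "tile": [1], "variant": ["p.Ala2Val"], "replicate": [1],
            "freq_pre": [f_pre], "freq_post": [f_post], "wt_freq": [f_wt],
            "count_pre": [200], "count_post": [50],
            "depth_pre": [D], "depth_post": [D], "wt_depth": [D], "wt_n": [1],
            "excluded": [False], "well_measured": [True],
        })
        se_delta = enrichment_scores(df)["se_log_phi"].iloc[0]

        rng = np.random.default_rng(12345)
        n = 100_000
        pre = rng.poisson(f_pre, n)
        post = rng.poisson(f_post, n)
        wt = rng.poisson(f_wt, n)
        ok = (pre - wt > 0) & (post - wt > 0)
        lr = np.log2((post[ok] - wt[ok]) / (pre[ok] - wt[ok]))
        assert se_delta == pytest.approx(lr.std(ddof=1), rel=0.05)


class TestRescale:
    def _rescaled(self):
        filt = apply_filters(compute_frequencies(toy_bundle()), TOY_CFG)
        return rescale_scores(enrichment_scores(filt), TOY_CFG)

    def test_anchor_medians_exact(self):
        out = self._rescaled()
        for rep, grp in out.groupby("replicate"):
            meas = grp[~grp["unmeasurable"]]
            assert meas.loc[meas["klass"] == "nonsense",
                            "score"].median() == pytest.approx(0.0, abs=1e-12)
            assert meas.loc[meas["klass"] == "synonymous",
                            "score"].median() == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        """Shifting/scaling all log-ratios leaves rescaled scores unchanged."""
        filt = apply_filters(compute_frequencies(toy_bundle()), TOY_CFG)
        enr = enrichment_scores(filt)
        base = rescale_scores(enr, TOY_CFG)
        warped = enr.copy()
        warped["log_phi"] = 3.0 * warped["log_phi"] - 7.0
        warped["se_log_phi"] = 3.0 * warped["se_log_phi"]
        again = rescale_scores(warped, TOY_CFG)
        pd.testing.assert_series_equal(base["score"], again["score"],
                                       atol=1e-12, rtol=1e-12)

    def test_no_separation_raises(self):
        filt = apply_filters(compute_frequencies(toy_bundle()), TOY_CFG)
        enr = enrichment_scores(filt)
        flipped = enr.copy()
        flipped["log_phi"] = -flipped["log_phi"]
        from mavemap.scoring import ScreenSeparationError
        with pytest.raises(ScreenSeparationError, match="no selection separation"):
            rescale_scores(flipped, TOY_CFG)

    def test_too_few_anchors_raises(self):
        filt = apply_filters(compute_frequencies(toy_bundle()), TOY_CFG)
        enr = enrichment_scores(filt)
        with pytest.raises(ValueError, match="anchors"):
            rescale_scores(enr, ScoringConfig(min_anchors=10))


class TestRegularize:
    def test_on_trend_errors_are_fixed_point(self):
        """All empirical ses exactly on the fitted trend stay unchanged."""
        rng = np.random.default_rng(0)
        f_pre = 10 ** rng.uniform(1, 3, 200)
        se = 3.0 * f_pre ** -0.5
        df = pd.DataFrame({
            "variant": [f"p.Ala{i+2}Val" for i in range(200)],
            "replicate": 1, "klass": "missense", "freq_pre": f_pre,
            "score": 1.0, "se": se, "df": 1.0, "unmeasurable": False,
            "well_measured": True,
        })
        out = regularize_errors(df, ScoringConfig(min_fit_variants=30))
        assert np.allclose(out["se"], se, rtol=1e-6)
        assert (out["df"] == 3.0).all()

    def test_zero_se_artifact_is_lifted(self):
        rng = np.random.default_rng(1)
        f_pre = 10 ** rng.uniform(1, 3, 100)
        se = 3.0 * f_pre ** -0.5
        se[0] = 0.0  # two identical replicate draws
        df = pd.DataFrame({
            "variant": [f"p.Ala{i+2}Val" for i in range(100)],
            "replicate": 1, "klass": "missense", "freq_pre": f_pre,
            "score": 1.0, "se": se, "df": 1.0, "unmeasurable": False,
            "well_measured": True,
        })
        out = regularize_errors(df, ScoringConfig(min_fit_variants=30))
        assert out["se"].iloc[0] > 0.0

    def test_trend_slope_recovered(self):
        """se ~ f_pre^(-1/2) data: LAD fit finds slope -0.5."""
        rng = np.random.default_rng(2)
        f_pre = 10 ** rng.uniform(1, 4, 500)
        se = 2.0 * f_pre ** -0.5 * np.exp(rng.normal(0, 0.1, 500))
        a, b = _lad_fit(np.log10(f_pre), np.log10(se))
        assert b == pytest.approx(-0.5, abs=0.05)

    def test_too_few_variants_warns_and_passes_through(self, caplog):
        df = pd.DataFrame({
            "variant": ["p.Ala2Val", "p.Ala3Val"], "replicate": 1,
            "klass": "missense", "freq_pre": [100.0, 200.0],
            "score": 1.0, "se": [0.1, 0.2], "df": 1.0,
            "unmeasurable": False, "well_measured": True,
        })
        import logging
        with caplog.at_level(logging.WARNING):
            out = regularize_errors(df, ScoringConfig(min_fit_variants=30))
        assert "unregularized" in caplog.text
        assert np.allclose(out["se"], [0.1, 0.2])


class TestCombine:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(rows, columns=["variant", "replicate", "klass",
                                           "score", "se", "df",
                                           "unmeasurable", "well_measured"])

    def test_equal_errors_average(self):
        out = combine_replicates(self._frame([
            ("p.Ala2Val", 1, "missense", 0.4, 0.1, 1.0, False, True),
            ("p.Ala2Val", 2, "missense", 0.6, 0.1, 1.0, False, True)]))
        assert out["score"].iloc[0] == pytest.approx(0.5)

    def test_inverse_variance_weights_closed_form(self):
        # weights 1/1 and 1/4: s = (0*1 + 1*0.25)/1.25 = 0.2
        out = combine_replicates(self._frame([
            ("p.Ala2Val", 1, "missense", 0.0, 1.0, 1.0, False, True),
            ("p.Ala2Val", 2, "missense", 1.0, 2.0, 1.0, False, True)]))
        assert out["score"].iloc[0] == pytest.approx(0.2)
        assert out["se"].iloc[0] == pytest.approx(np.sqrt(1 / 1.25))

    def test_single_replicate_passthrough(self):
        out = combine_replicates(self._frame([
            ("p.Ala2Val", 1, "missense", 0.7, 0.1, 1.0, False, True),
            ("p.Ala2Val", 2, "missense", np.nan, np.nan, 1.0, True, False)]))
        assert out["score"].iloc[0] == 0.7
        assert out["se"].iloc[0] == 0.1
        assert out["df"].iloc[0] == 1.0
        assert out["n_replicates"].iloc[0] == 1

    def test_zero_measurable_absent(self):
        out = combine_replicates(self._frame([
            ("p.Ala2Val", 1, "missense", np.nan, np.nan, 1.0, True, False)]))
        assert len(out) == 0

    def test_combined_within_replicate_range_and_tighter(self, growth_counts,
                                                         effects):
        from mavemap.scoring import (apply_filters, compute_frequencies,
                                     enrichment_scores, rescale_scores)
        cfg = ScoringConfig()
        filt = apply_filters(compute_frequencies(growth_counts), cfg)
        info = effects.drop_duplicates("variant").set_index("variant")
        filt["klass"] = filt["variant"].map(info["klass"])
        resc = rescale_scores(enrichment_scores(filt), cfg)
        combined = combine_replicates(resc)
        per_rep = resc[~resc["unmeasurable"]].groupby("variant").agg(
            lo=("score", "min"), hi=("score", "max"),
            min_se=("se", "min"), n=("score", "size"))
        both = combined.merge(per_rep, on="variant")
        multi = both[both["n"] >= 2]
        eps = 1e-12
        assert (multi["score"] >= multi["lo"] - eps).all()
        assert (multi["score"] <= multi["hi"] + eps).all()
        assert (multi["se"] <= multi["min_se"] + eps).all()


class TestSpreadsheetOracle:
    """Every stage matches a flat independent recomputation to 1e-12."""

    def test_replicate_scores_match(self):
        filt = apply_filters(compute_frequencies(toy_bundle()), TOY_CFG)
        resc = rescale_scores(enrichment_scores(filt), TOY_CFG)
        rep_scores, _ = spreadsheet_scores()
        for _, row in resc.iterrows():
            expected = rep_scores[row["replicate"]].get(row["variant"])
            if row["unmeasurable"]:
                assert expected is None
            else:
                assert row["score"] == pytest.approx(expected[0], rel=1e-12)
                assert row["se"] == pytest.approx(expected[1], rel=1e-12)

    def test_combined_map_matches(self):
        vmap = score_pipeline(toy_bundle(), TOY_CFG)
        _, combined = spreadsheet_scores()
        assert set(vmap["variant"]) == set(combined)
        for _, row in vmap.iterrows():
            s, se = combined[row["variant"]]
            assert row["score"] == pytest.approx(s, rel=1e-12)
            assert row["se"] == pytest.approx(se, rel=1e-12)


class TestPipeline:
    def test_bimodal_modes_near_anchors(self, effect_map):
        mis = effect_map[(effect_map["klass"] == "missense") &
                         effect_map["well_measured"]]
        hist, edges = np.histogram(mis["score"], bins=np.arange(-0.5, 1.55, 0.1))
        centers = (edges[:-1] + edges[1:]) / 2
        low = centers < 0.5
        mode_low = centers[low][np.argmax(hist[low])]
        mode_high = centers[~low][np.argmax(hist[~low])]
        assert abs(mode_low - 0.0) <= 0.15
        assert abs(mode_high - 1.0) <= 0.15

    def test_null_screen_unimodal_near_one(self, space):
        from mavemap.simulate import (SimulationConfig, simulate_screen,
                                      simulate_true_effects)
        cfg = SimulationConfig(seed=21, selection_fold=1.0)
        eff = simulate_true_effects(space, cfg)
        counts = simulate_screen(eff, cfg, assay="growth")
        # a B=1 screen has no nonsense/synonymous separation and must refuse
        from mavemap.scoring import ScreenSeparationError
        with pytest.raises((ScreenSeparationError, ValueError)):
            score_pipeline(counts, variant_info=eff)

    def test_parameter_recovery(self, effect_map, effects):
        merged = effect_map.merge(effects[["variant", "true_score"]],
                                  on="variant")
        wm = merged[(merged["klass"] == "missense") & merged["well_measured"]]
        r = np.corrcoef(wm["score"], wm["true_score"])[0, 1]
        assert len(wm) > 2000
        assert r >= 0.9

    def test_scorer_estimator_api(self, growth_counts, effects):
        from sklearn.base import clone
        scorer = TileSeqScorer(min_count=10)
        assert clone(scorer).get_params()["min_count"] == 10
        vmap = scorer.fit_transform(growth_counts, variant_info=effects)
        assert {"variant", "score", "se", "df"} <= set(vmap.columns)
        assert scorer.anchors_
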