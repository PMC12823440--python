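import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kindeg import scoring as sc
from kindeg import simulate as sim
from conftest import make_tensor

TPS = (2.0, 6.0, 10.0, 14.0, 18.0)


def _inert_panel(n_lines=3, n_comp=4):
    return {
        (f"KIN{li:03d}", f"c{ci}"): [100.0] * 5
        for li in range(1, n_lines + 1)
        for ci in range(1, n_comp + 1)
    }


class TestVarianceFilter:
    def _tensor(self, sds):
        vals = {("KIN001", "c1"): [100.0] * 5, ("KIN001", "c2"): [100.0] * 5}
        return make_tensor(vals, {("KIN001", "c1"): sds})

    def test_high_sd_at_all_timepoints_excluded(self):
        t = self._tensor([31.0] * 5)
        n, _ = sc.filter_variable_pairs(t)
        assert n == 1
        assert t.exclusions.loc[("KIN001", "c1"), "variance_filtered"]

    def test_one_quiet_timepoint_retains_pair(self):
        t = self._tensor([31.0, 31.0, 31.0, 31.0, 29.0])
        n, _ = sc.filter_variable_pairs(t)
        assert n == 0

    def test_threshold_is_strict(self):
        t = self._tensor([0.0] * 5)
        t.rep_sd.loc[("KIN001", "c1")] = 30.0  # exactly at the boundary
        n, _ = sc.filter_variable_pairs(t)
        assert n == 0

    def test_zero_high_sd_fraction(self):
        t = self._tensor([31.0, 0.0, 0.0, 0.0, 0.0])
        _, frac = sc.filter_variable_pairs(t)
        assert frac == pytest.approx(0.5)  # c2 has zero high-sd timepoints, c1 one


class TestReactiveFilter:
    def _tensor(self, anchor_by_line, comp="c1", n_extra=0):
        vals = {
            (line, comp): [a] + [100.0] * 4 for line, a in anchor_by_line.items()
        }
        for li, line in enumerate(anchor_by_line):
            vals[(line, "cX")] = [100.0] * 5
        return make_tensor(vals, centered=False)

    def test_uniformly_low_compound_excluded(self):
        t = self._tensor({f"K{i}": 60.0 for i in range(5)})
        assert sc.filter_reactive_compounds(t) == ["c1"]

    def test_median_exactly_70_retained(self):
        t = self._tensor({f"K{i}": 70.0 for i in range(5)})
        assert sc.filter_reactive_compounds(t) == []

    def test_median_is_robust_to_one_low_line(self):
        anchors = {f"K{i}": 100.0 for i in range(9)}
        anchors["K9"] = 10.0
        t = self._tensor(anchors)
        assert sc.filter_reactive_compounds(t) == []

    def test_few_lines_not_evaluated(self):
        t = self._tensor({"K0": 10.0, "K1": 10.0})
        assert sc.filter_reactive_compounds(t) == []

    def test_refuses_centered_tensor(self):
        t = self._tensor({f"K{i}": 60.0 for i in range(5)})
        t.centered = True
        with pytest.raises(ValueError):
            sc.filter_reactive_compounds(t)


class TestCenterSeries:
    def test_single_series_shifted_to_100(self):
        t = make_tensor({("KIN001", "c1"): [90.0, 80.0, 70.0, 60.0, 50.0]},
                        centered=False)
        c = sc.center_series(t)
        assert np.allclose(c.values.loc[("KIN001", "c1")],
                           [100.0, 90.0, 80.0, 70.0, 60.0])

    def test_already_centered_unchanged(self):
        t = make_tensor(_inert_panel(), centered=False)
        c = sc.center_series(t)
        assert np.allclose(c.values.to_numpy(), 100.0, atol=1e-9)

    def test_planted_offsets_removed(self):
        rng = np.random.default_rng(4)
        lines = [f"KIN{i:03d}" for i in range(1, 8)]
        comps = [f"c{i}" for i in range(1, 10)]
        a = {l: rng.normal(0, 10) for l in lines}
        b = {c: rng.normal(0, 10) for c in comps}
        base = np.array([100.0, 90.0, 80.0, 70.0, 60.0])
        vals = {(l, c): base + a[l] + b[c] for l in lines for c in comps}
        c = sc.center_series(make_tensor(vals, centered=False))
        for pair, row in c.values.iterrows():
            assert np.allclose(row.to_numpy(), base, atol=1e-6)

    def test_missing_anchor_uses_earliest_timepoint(self):
        t = make_tensor({("KIN001", "c1"): [np.nan, 80.0, 70.0, 60.0, 50.0]},
                        centered=False)
        c = sc.center_series(t)
        assert c.anchor_flags.loc[("KIN001", "c1")]
        assert c.values.loc[("KIN001", "c1"), 6.0] == pytest.approx(100.0)


def _null_fixture(dmso_wells=None, chx_wells=None, extra_pairs=None):
    pairs = _inert_panel(3, 6)
    if extra_pairs:
        pairs.update(extra_pairs)
    lines = sorted({l for l, _ in pairs})
    ctl = {}
    for line in lines:
        if dmso_wells is not None:
            ctl[(line, "DMSO")] = dmso_wells
        if chx_wells is not None:
            ctl[(line, "CHX")] = chx_wells.get(line) if isinstance(chx_wells, dict) else chx_wells
    return make_tensor(pairs, control_wells=ctl)


class TestNullModels:
    def test_constant_dmso_gives_floored_scale(self):
        t = _null_fixture(dmso_wells=[[100.0] * 5] * 3)
        nm = sc.build_null_models(t)
        loc = nm.loc[("DMSO", "")]
        scale = nm.scale[("DMSO", "")]
        assert np.allclose(loc.to_numpy(), 100.0)
        assert np.allclose(scale.to_numpy(), sc.SCALE_FLOOR)

    def test_chx_location_matches_generator_closed_form(self):
        hl = 1.5
        traj = sim.turnover_trajectory(hl, 1.0, "translation_shutoff", list(TPS))
        t = _null_fixture(dmso_wells=[[100.0] * 5] * 3,
                          chx_wells=[list(traj)] * 3)
        nm = sc.build_null_models(t)
        loc = nm.loc[("CHX", "")]
        assert loc.loc["KIN001", 6.0] == pytest.approx(100 * np.exp(-np.log(2) / 1.5 * 6), rel=1e-9)
        assert loc.loc["KIN001", 6.0] == pytest.approx(6.25, abs=0.01)

    def test_delta_variant_of_constant_is_zero(self):
        t = _null_fixture(dmso_wells=[[100.0] * 5] * 3)
        nm = sc.build_null_models(t)
        assert np.allclose(nm.loc[("DMSO", "_2h")].to_numpy(), 0.0)


def brute_force_scores(tensor, nulls, direction, sigma=2.0):
    """Independent per-(pair, scheme, timepoint) recomputation with loops."""
    schemes = sc.DEGRADATION_SCHEMES if direction == "degradation" else sc.STABILIZATION_SCHEMES
    tps = list(tensor.timepoints)
    v = tensor.values
    lib = [
        p for p in v.index
        if p[1] not in tensor.control_compounds and not v.loc[[p]].isna().all(axis=1).iloc[0]
    ]

    # reference samples per (line, basis, variant, timepoint), from raw data
    ctl = tensor.control_values
    refs = {}
    for basis in ("DMSO", "CHX", "NVP2"):
        ids = [c for c, r in tensor.control_compounds.items() if r == basis]
        sub = ctl[ctl.compound_id.isin(ids)]
        for line in v.index.get_level_values(0).unique():
            wells = {}
            for _, row in sub[sub.cell_line_id == line].iterrows():
                wells.setdefault(row.well_key, {})[row.timepoint_h] = row.poc
            for t in tps:
                plain = [w[t] for w in wells.values() if t in w]
                delta = [w[t] - w[tps[0]] for w in wells.values() if t in w and tps[0] in w]
                refs[(line, basis, "", t)] = plain
                refs[(line, basis, "_2h", t)] = delta

    def loc_scale(sample):
        if len(sample) < 2:
            return np.nan, sc.SCALE_FLOOR
        m = float(np.mean(sample))
        s = float(np.std(sample, ddof=1))
        return m, max(s, sc.SCALE_FLOOR)

    rows = {}
    for pair in lib:
        line, comp = pair
        series = v.loc[pair]
        anchor_t = tps[0] if not np.isnan(series[tps[0]]) else [
            t for t in tps if not np.isnan(series[t])
        ][0]
        anchor = series[anchor_t]
        counts = {}
        n_present = int(series.notna().sum())
        for scheme in schemes:
            basis = scheme.split("_")[0]
            variant = "_2h" if scheme.endswith("_2h") else ""
            cnt = 0
            for t in tps:
                val = series[t]
                if np.isnan(val):
                    continue
                x = val - anchor if variant else val
                if basis == "CPD":
                    others = []
                    for (l2, c2) in lib:
                        if l2 != line or c2 == comp:
                            continue
                        s2 = v.loc[(l2, c2)]
                        if np.isnan(s2[t]):
                            continue
                        if variant:
                            at2 = tps[0] if not np.isnan(s2[tps[0]]) else [
                                u for u in tps if not np.isnan(s2[u])
                            ][0]
                            others.append(s2[t] - s2[at2])
                        else:
                            others.append(s2[t])
                    loc, scale = loc_scale(others)
                else:
                    loc, scale = loc_scale(refs[(line, basis, variant, t)])
                if np.isnan(loc):
                    continue
                z = (x - loc) / scale
                if direction == "degradation" and z <= -sigma:
                    cnt += 1
                if direction == "stabilization" and z >= sigma:
                    cnt += 1
            if n_present < len(tps):
                cnt = min(cnt + 1, 5)
            counts[scheme] = cnt
        counts["TOT"] = sum(counts[s] for s in schemes)
        rows[pair] = counts
    out = pd.DataFrame(rows).T
    out.index.names = ["cell_line_id", "compound_id"]
    return out


class TestSchemeScores:
    def _fixture(self):
        rng = np.random.default_rng(9)
        pairs = {}
        for li in range(1, 4):
            for ci in range(1, 8):
                pairs[(f"KIN{li:03d}", f"c{ci}")] = list(
                    100 + rng.normal(0, 3, 5)
                )
        pairs[("KIN001", "c1")] = [95.0, 60.0, 40.0, 30.0, 20.0]  # degrader-like
        pairs[("KIN002", "c2")] = [90.0, np.nan, 40.0, 30.0, 20.0]  # missing tp
        dmso = [list(100 + rng.normal(0, 2, 5)) for _ in range(4)]
        chx = [list(sim.turnover_trajectory(2.0, 1.0, "translation_shutoff", list(TPS))
                    * np.exp(rng.normal(0, 0.03, 5))) for _ in range(4)]
        nvp = [list(sim.turnover_trajectory(3.0, 1.0, "transcription_shutoff", list(TPS))
                    * np.exp(rng.normal(0, 0.03, 5))) for _ in range(4)]
        ctl = {}
        for line in ("KIN001", "KIN002", "KIN003"):
            ctl[(line, "DMSO")] = dmso
            ctl[(line, "CHX")] = chx
            ctl[(line, "NVP2")] = nvp
        return make_tensor(pairs, control_wells=ctl)

    def test_value_at_null_location_scores_zero(self):
        t = _null_fixture(dmso_wells=[[100.0, 101.0, 99.0, 100.0, 100.0],
                                      [101.0, 100.0, 100.0, 99.0, 101.0],
                                      [99.0, 99.0, 101.0, 101.0, 99.0]])
        nm = sc.build_null_models(t)
        scores = sc.compute_scheme_scores(t, nm, "degradation")
        for s in ("DMSO_norm", "DMSO_norm_2h", "CPD_norm", "CPD_norm_2h"):
            assert (scores[s] == 0).all()

    def test_three_sigma_drop_scores_five(self):
        pairs = _inert_panel(3, 6)
        pairs[("KIN001", "c1")] = [97.0] * 5  # 3 scales below a sd-1 DMSO null
        dmso = [[99.0] * 5, [100.0] * 5, [101.0] * 5]
        ctl = {(l, "DMSO"): dmso for l in ("KIN001", "KIN002", "KIN003")}
        t = make_tensor(pairs, control_wells=ctl)
        nm = sc.build_null_models(t)
        scores = sc.compute_scheme_scores(t, nm, "degradation")
        assert scores.loc[("KIN001", "c1"), "DMSO_norm"] == 5
        assert scores.loc[("KIN002", "c1"), "DMSO_norm"] == 0

    def test_missing_timepoint_correction_caps_at_five(self):
        t = self._fixture()
        nm = sc.build_null_models(t)
        scores = sc.compute_scheme_scores(t, nm, "degradation")
        row = scores.loc[("KIN002", "c2")]
        assert row["missing_timepoint"]
        # 4 significant observed timepoints +1 correction -> capped 5
        assert row["DMSO_norm"] == 5

    def test_matches_brute_force_oracle(self):
        t = self._fixture()
        nm = sc.build_null_models(t)
        for direction in ("degradation", "stabilization"):
            fast = sc.compute_scheme_scores(t, nm, direction)
            slow = brute_force_scores(t, nm, direction)
            schemes = (sc.DEGRADATION_SCHEMES if direction == "degradation"
                       else sc.STABILIZATION_SCHEMES)
            fast = fast.sort_index()
            slow = slow.reindex(fast.index)
            for s in (*schemes, "TOT"):
                assert (fast[s].to_numpy() == slow[s].to_numpy()).all(), (direction, s)

    def test_scores_bounded(self, tiny_noisy_result):
        res, _ = tiny_noisy_result
        for scores, schemes in (
            (res.degradation_scores, sc.DEGRADATION_SCHEMES),
            (res.stabilization_scores, sc.STABILIZATION_SCHEMES),
        ):
            mat = scores[list(schemes)].to_numpy()
            assert mat.min() >= 0 and mat.max() <= 5
            assert (scores["TOT"] == mat.sum(axis=1)).all()


class TestHitQuery:
    def _scores(self, **overrides):
        base = {s: 0 for s in sc.DEGRADATION_SCHEMES}
        base.update(overrides)
        df = pd.DataFrame([base], index=pd.MultiIndex.from_tuples(
            [("KIN001", "c1")], names=["cell_line_id", "compound_id"]))
        df["TOT"] = df[list(sc.DEGRADATION_SCHEMES)].sum(axis=1)
        df["missing_timepoint"] = False
        return df

    def test_dmso_clause_alone_hits(self):
        hit, trig = sc.DEFAULT_DEGRADATION_QUERY.evaluate(self._scores(DMSO_norm=5))
        assert hit.iloc[0] and "DMSO_norm>=5" in trig.iloc[0]

    def test_all_zero_is_not_a_hit(self):
        hit, _ = sc.DEFAULT_DEGRADATION_QUERY.evaluate(self._scores())
        assert not hit.iloc[0]

    def test_tot_clause_catches_diffuse_signal(self):
        # no single clause passes, but the eight schemes sum past 10
        hit, trig = sc.DEFAULT_DEGRADATION_QUERY.evaluate(
            self._scores(DMSO_norm=4, CHX_norm=1, CPD_norm=4,
                         CHX_norm_2h=1, NVP2_norm=2)
        )
        assert hit.iloc[0] and trig.iloc[0] == "TOT>=10"

    def test_unknown_scheme_is_config_error(self):
        q = sc.HitQuery(clauses=(("NOPE", 1),))
        with pytest.raises(ValueError):
            q.evaluate(self._scores())

    @given(
        scores=st.lists(
            st.tuples(*[st.integers(0, 5)] * 8), min_size=1, max_size=30
        ),
        bump=st.sampled_from(["DMSO_norm", "CHX_norm", "CPD_norm", "CHX_norm_2h", "TOT"]),
    )
    @settings(derandomize=True, deadline=None, max_examples=100)
    def test_raising_any_threshold_never_adds_hits(self, scores, bump):
        idx = pd.MultiIndex.from_tuples(
            [("K", f"c{i}") for i in range(len(scores))],
            names=["cell_line_id", "compound_id"],
        )
        df = pd.DataFrame(scores, columns=list(sc.DEGRADATION_SCHEMES), index=idx)
        df["TOT"] = df.sum(axis=1)
        q1 = sc.DEFAULT_DEGRADATION_QUERY
        if bump == "TOT":
            q2 = sc.HitQuery(clauses=q1.clauses, tot_threshold=q1.tot_threshold + 1)
        else:
            q2 = sc.HitQuery(
                clauses=tuple((s, thr + (s == bump)) for s, thr in q1.clauses),
                tot_threshold=q1.tot_threshold,
            )
        h1, _ = q1.evaluate(df)
        h2, _ = q2.evaluate(df)
        assert not (h2 & ~h1).any()


class TestCallHits:
    def test_promiscuous_compound_dropped(self):
        pairs = {(f"KIN{i:03d}", "bad"): [90.0, 20.0, 10.0, 5.0, 5.0] for i in range(1, 13)}
        pairs.update({(f"KIN{i:03d}", f"c{i}"): [100.0] * 5 for i in range(1, 13)})
        dmso = [[99.0] * 5, [100.0] * 5, [101.0] * 5]
        ctl = {(f"KIN{i:03d}", "DMSO"): dmso for i in range(1, 13)}
        t = make_tensor(pairs, control_wells=ctl)
        nm = sc.build_null_models(t)
        scores = sc.compute_scheme_scores(t, nm, "degradation")
        q = sc.HitQuery(clauses=(("DMSO_norm", 5),), tot_threshold=None)
        hits = sc.call_hits(scores, q, t, promiscuity_threshold=10)
        sub = hits.xs("bad", level="compound_id")
        assert sub["raw_hit"].sum() == 12
        assert sub["excl_promiscuous"].all()
        assert not hits["hit"].any()

    def test_eleven_kinase_threshold_is_strict(self):
        pairs = {(f"KIN{i:03d}", "bad"): [90.0, 20.0, 10.0, 5.0, 5.0] for i in range(1, 11)}
        dmso = [[99.0] * 5, [100.0] * 5, [101.0] * 5]
        ctl = {(f"KIN{i:03d}", "DMSO"): dmso for i in range(1, 11)}
        t = make_tensor(pairs, control_wells=ctl)
        nm = sc.build_null_models(t)
        scores = sc.compute_scheme_scores(t, nm, "degradation")
        q = sc.HitQuery(clauses=(("DMSO_norm", 5),), tot_threshold=None)
        hits = sc.call_hits(scores, q, t, promiscuity_threshold=10)
        # exactly 10 kinase hits: not promiscuous (> 10 is strict)
        assert hits["hit"].sum() == 10

    def test_control_line_scorer_excluded_for_stabilization(self):
        pairs = {
            ("GFP", "s1"): [110.0, 150.0, 160.0, 170.0, 180.0],
            ("KIN001", "s1"): [110.0, 150.0, 160.0, 170.0, 180.0],
            ("KIN001", "c2"): [100.0] * 5,
        }
        dmso = [[99.0] * 5, [100.0] * 5, [101.0] * 5]
        ctl = {(l, "DMSO"): dmso for l in ("GFP", "KIN001")}
        t = make_tensor(pairs, control_wells=ctl)
        nm = sc.build_null_models(t)
        scores = sc.compute_scheme_scores(t, nm, "stabilization")
        q = sc.HitQuery("stabilization", (("DMSO_norm", 5),), None)
        hits = sc.call_hits(scores, q, t)
        assert hits.loc[("KIN001", "s1"), "excl_control_scorer"]
        assert not hits["hit"].any()

    def test_curated_exclusion_blocks_hit(self):
        pairs = {("KIN001", "c1"): [90.0, 20.0, 10.0, 5.0, 5.0]}
        dmso = [[99.0] * 5, [100.0] * 5, [101.0] * 5]
        t = make_tensor(pairs, control_wells={("KIN001", "DMSO"): dmso})
        nm = sc.build_null_models(t)
        scores = sc.compute_scheme_scores(t, nm, "degradation")
        q = sc.HitQuery(clauses=(("DMSO_norm", 5),), tot_threshold=None)
        assert sc.call_hits(scores, q, t)["hit"].sum() == 1
        hits = sc.call_hits(scores, q, t, curated_exclusions={"c1"})
        assert hits["hit"].sum() == 0 and hits["excl_curated"].all()


class TestThresholdScan:
    def _scores(self, tensor):
        nm = sc.build_null_models(tensor)
        return sc.compute_scheme_scores(tensor, nm, "degradation")

    def test_clean_screen_reaches_zero_fdr(self, tiny_result):
        res, truth = tiny_result
        ref = truth.protac_pairs()
        query, curve = sc.scan_thresholds(res.degradation_scores, ref)
        hit, _ = query.evaluate(res.degradation_scores)
        assert set(res.degradation_scores.index[hit]) >= ref
        full = curve[curve.recall == 1.0]
        assert full["fdr"].min() == pytest.approx(0.0)

    def test_returned_query_minimizes_fdr_over_grid(self, tiny_noisy_result):
        res, truth = tiny_noisy_result
        ref = truth.protac_pairs()
        query, curve = sc.scan_thresholds(res.degradation_scores, ref)
        full = curve[curve.recall == 1.0]
        assert len(full) > 0
        thr = dict(query.clauses)
        row = full[
            (full.DMSO_norm == thr["DMSO_norm"]) & (full.CHX_norm == thr["CHX_norm"])
            & (full.CPD_norm == thr["CPD_norm"]) & (full.CHX_norm_2h == thr["CHX_norm_2h"])
            & (full.TOT == query.tot_threshold)
        ]
        assert row["fdr"].iloc[0] == pytest.approx(full["fdr"].min())

    def test_empty_reference_is_an_error(self, tiny_result):
        res, _ = tiny_result
        with pytest.raises(ValueError):
            sc.scan_thresholds(res.degradation_scores, set())
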