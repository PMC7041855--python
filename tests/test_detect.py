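import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from ampcnv import (
    AmpliconStatus,
    CnvEvent,
    DetectionConfig,
    NormalizationConfig,
    SimulationSpec,
    State,
    apply_cnv,
    call_segments,
    classify,
    merge_segments,
    simulate_run,
    two_stage_detect,
    z_scores,
)
from ampcnv.simulate import gene_region, make_design

from conftest import single_chrom_design


class TestZScores:
    def test_hand_computed_pair(self):
        # mean 1, population SD 0.2
        np.testing.assert_allclose(z_scores(np.array([0.8, 1.2])), [-1.0, 1.0])

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            z_scores(np.array([1.0, 1.0, 1.0]))

    def test_single_value_is_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            z_scores(np.array([1.0, np.nan]))

    def test_nan_propagates(self):
        z = z_scores(np.array([0.8, np.nan, 1.2]))
        assert np.isnan(z[1]) and np.isfinite(z[[0, 2]]).all()

    @given(st.lists(st.floats(min_value=0.01, max_value=10.0), min_size=2,
                    max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_standardization_identity(self, values):
        arr = np.array(values)
        # skip (near-)constant inputs: sigma below float noise makes the
        # standardization numerically meaningless and sigma=0 is an error
        if arr.std() <= 1e-9 * max(1.0, abs(arr.mean())):
            return
        z = z_scores(arr)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9


class TestClassify:
    def test_z_past_default_quantile_is_del(self):
        d = single_chrom_design(1)
        # Phi^-1(0.99) ~ 2.3263 < 2.40
        [st_] = classify(np.array([-2.40]), d, alpha=0.01)
        assert st_.state is State.DEL

    def test_stricter_alpha_neutralizes(self):
        d = single_chrom_design(1)
        # Phi^-1(0.999) ~ 3.09 > 2.40
        [st_] = classify(np.array([-2.40]), d, alpha=0.001)
        assert st_.state is State.NEUTRAL

    def test_zero_z_always_neutral(self):
        d = single_chrom_design(1)
        for alpha in (0.4, 0.05, 0.01):
            [st_] = classify(np.array([0.0]), d, alpha=alpha)
            assert st_.state is State.NEUTRAL

    def test_positive_significant_is_dup(self):
        d = single_chrom_design(1)
        [st_] = classify(np.array([3.5]), d, alpha=0.01)
        assert st_.state is State.DUP

    def test_tie_at_alpha_counts(self):
        d = single_chrom_design(1)
        q = norm.ppf(0.99)
        [st_] = classify(np.array([-q]), d, alpha=0.01)
        assert st_.state is State.DEL

    def test_nan_becomes_missing(self):
        d = single_chrom_design(2)
        states = classify(np.array([np.nan, 1.0]), d, alpha=0.01)
        assert states[0].state is State.MISSING


def statuses_from_states(design, states):
    """Build a status list from symbolic states with consistent z values."""
    z_for = {State.DEL: -3.5, State.DUP: 3.5, State.NEUTRAL: 0.0}
    out = []
    for amp_id, s in zip(design.ids, states):
        if s is State.MISSING:
            out.append(AmpliconStatus(amp_id, float("nan"), float("nan"), s))
        else:
            z = z_for[s]
            out.append(AmpliconStatus(amp_id, z, float(norm.sf(abs(z))), s))
    return out


def oracle_segments(design, states, min_amplicons):
    """Brute-force caller: enumerate every window of every length >=
    min_amplicons and keep maximal significant same-direction runs."""
    found = set()
    blocks = design.chromosome_blocks()
    for chrom, idxs in blocks.items():
        visible = [i for i in idxs if states[i] is not State.MISSING]
        n = len(visible)
        for lo in range(n):
            for hi in range(lo + min_amplicons - 1, n):
                window = visible[lo:hi + 1]
                direction = states[window[0]]
                if direction not in (State.DEL, State.DUP):
                    continue
                if any(states[i] is not direction for i in window):
                    continue
                left_ext = lo > 0 and states[visible[lo - 1]] is direction
                right_ext = hi < n - 1 and states[visible[hi + 1]] is direction
                if left_ext or right_ext:
                    continue  # not maximal
                found.add((direction, tuple(window)))
    return found


class TestCallSegments:
    def test_three_del_run_is_called(self):
        d = single_chrom_design(3)
        statuses = statuses_from_states(d, [State.DEL] * 3)
        calls = call_segments(statuses, d, DetectionConfig())
        assert len(calls) == 1
        call = calls[0]
        assert call.direction is State.DEL and call.n_amplicons == 3
        assert call.start == d[0].start and call.end == d[2].end

    def test_two_del_below_minimum(self):
        d = single_chrom_design(2)
        statuses = statuses_from_states(d, [State.DEL] * 2)
        assert call_segments(statuses, d, DetectionConfig()) == []

    def test_run_never_spans_chromosomes(self):
        d = make_design([1, 1, 1], ["GA", "GB", "GC"], n_chromosomes=3)
        statuses = statuses_from_states(d, [State.DEL] * 3)
        assert call_segments(statuses, d, DetectionConfig()) == []

    def test_missing_amplicons_are_transparent(self):
        d = single_chrom_design(5)
        states = [State.DEL, State.MISSING, State.DEL, State.MISSING, State.DEL]
        statuses = statuses_from_states(d, states)
        calls = call_segments(statuses, d, DetectionConfig())
        assert len(calls) == 1 and calls[0].n_amplicons == 3

    def test_direction_change_splits_runs(self):
        d = single_chrom_design(6)
        states = [State.DEL] * 3 + [State.DUP] * 3
        calls = call_segments(statuses_from_states(d, states), d, DetectionConfig())
        assert [c.direction for c in calls] == [State.DEL, State.DUP]

    @given(
        states=st.lists(
            st.sampled_from([State.DEL, State.DUP, State.NEUTRAL, State.MISSING]),
            min_size=1, max_size=60,
        ),
        min_amps=st.integers(min_value=1, max_value=4),
        split=st.booleans(),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_oracle(self, states, min_amps, split):
        n = len(states)
        if split and n > 1:
            half = n // 2
            d = make_design([max(half, 1), n - half], ["GA", "GB"],
                            n_chromosomes=2)
        else:
            d = single_chrom_design(n)
        statuses = statuses_from_states(d, states)
        cfg = DetectionConfig(min_amplicons=min_amps)
        calls = call_segments(statuses, d, cfg)
        got = {
            (c.direction, tuple(d.index[a] for a in c.amplicon_ids))
            for c in calls
        }
        assert got == oracle_segments(d, states, min_amps)


class TestMergeSegments:
    def layout(self, gap_z):
        d = single_chrom_design(7)
        z = np.array([-3.5, -3.5, -3.5, gap_z, -3.5, -3.5, -3.5])
        statuses = classify(z, d, alpha=0.01)
        cfg = DetectionConfig()
        calls = call_segments(statuses, d, cfg)
        return d, statuses, cfg, calls

    def test_single_gap_merges_at_relaxed_alpha(self):
        # Phi(-1.8) ~ 0.036 <= 0.05
        d, statuses, cfg, calls = self.layout(-1.8)
        assert len(calls) == 2
        merged = merge_segments(calls, statuses, d, cfg)
        assert len(merged) == 1
        assert merged[0].n_amplicons == 7 and merged[0].merged
        assert statuses[3].state is State.MERGED_GAP

    def test_weak_gap_does_not_merge(self):
        # Phi(-1.0) ~ 0.159 > 0.05
        d, statuses, cfg, calls = self.layout(-1.0)
        merged = merge_segments(calls, statuses, d, cfg)
        assert len(merged) == 2
        assert statuses[3].state is State.NEUTRAL

    def test_opposite_directions_never_merge(self):
        d = single_chrom_design(7)
        z = np.array([-3.5, -3.5, -3.5, -1.8, 3.5, 3.5, 3.5])
        statuses = classify(z, d, alpha=0.01)
        cfg = DetectionConfig()
        calls = call_segments(statuses, d, cfg)
        merged = merge_segments(calls, statuses, d, cfg)
        assert len(merged) == 2
        assert {c.direction for c in merged} == {State.DEL, State.DUP}

    def test_two_gap_amplicons_block_single_gap_rule(self):
        d = single_chrom_design(8)
        z = np.array([-3.5] * 3 + [-1.8, -1.8] + [-3.5] * 3)
        statuses = classify(z, d, alpha=0.01)
        cfg = DetectionConfig()
        calls = call_segments(statuses, d, cfg)
        assert len(merge_segments(calls, statuses, d, cfg)) == 2

    def test_distance_rule_merges_wider_gaps(self):
        d = single_chrom_design(8)
        z = np.array([-3.5] * 3 + [0.0, 0.0] + [-3.5] * 3)
        cfg = DetectionConfig(max_merge_distance=10_000)
        statuses = classify(z, d, alpha=0.01)
        calls = call_segments(statuses, d, cfg)
        merged = merge_segments(calls, statuses, d, cfg)
        assert len(merged) == 1 and merged[0].n_amplicons == 8

    def test_distance_rule_respects_limit(self):
        d = single_chrom_design(8)
        z = np.array([-3.5] * 3 + [0.0, 0.0] + [-3.5] * 3)
        cfg = DetectionConfig(max_merge_distance=100)  # gap is ~2000 bp
        statuses = classify(z, d, alpha=0.01)
        calls = call_segments(statuses, d, cfg)
        assert len(merge_segments(calls, statuses, d, cfg)) == 2

    def test_chained_merging_reaches_fixed_point(self):
        d = single_chrom_design(11)
        z = np.array([-3.5] * 3 + [-1.8] + [-3.5] * 3 + [-1.8] + [-3.5] * 3)
        statuses = classify(z, d, alpha=0.01)
        cfg = DetectionConfig()
        calls = call_segments(statuses, d, cfg)
        merged = merge_segments(calls, statuses, d, cfg)
        assert len(merged) == 1 and merged[0].n_amplicons == 11

    @given(st.lists(st.sampled_from([-3.5, -1.8, 0.0, 1.8, 3.5]),
                    min_size=3, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_merge_is_idempotent_and_direction_safe(self, zs):
        d = single_chrom_design(len(zs))
        statuses = classify(np.array(zs), d, alpha=0.01)
        cfg = DetectionConfig()
        calls = call_segments(statuses, d, cfg)
        once = merge_segments(calls, statuses, d, cfg)
        twice = merge_segments(list(once), statuses, d, cfg)
        assert [c.amplicon_ids for c in twice] == [c.amplicon_ids for c in once]
        assert len(once) >= 1 if calls else len(once) == 0
        for c in once:
            assert c.direction in (State.DEL, State.DUP)


class TestTwoStage:
    def test_no_cnv_run_yields_no_calls_both_stages(self, panel_design):
        run = simulate_run(SimulationSpec(design=panel_design, n_samples=6,
                                          noise_cv=0.0,
                                          amplicon_efficiency_sd=0.0, seed=3))
        # tiny noise to avoid zero variance
        run.counts[0, :] += np.arange(6)
        res = two_stage_detect(run)
        assert all(not v for v in res.calls.values())
        assert all(not v for v in res.stage1_calls.values())

    def test_shared_deletion_stage2_cleans_non_carriers(self):
        # 3 of 7 samples share a 39-amplicon deletion; after stage 2 no DUP
        # appears in non-carriers and every carrier keeps a DEL call.
        sizes = [39] + [10] * 27
        names = ["GDEL"] + [f"F{i}" for i in range(27)]
        design = make_design(sizes, names, n_chromosomes=6)
        spec = SimulationSpec(design=design, n_samples=7, noise_cv=0.03, seed=11)
        run = simulate_run(spec)
        region = gene_region(design, "GDEL")
        carriers = ["S1", "S2", "S3"]
        for sid in carriers:
            run = apply_cnv(run, CnvEvent(sid, region, copy_number=1))
        res = two_stage_detect(run, NormalizationConfig(min_raw_reads=0))
        idx = design.gene_indices("GDEL")
        chrom = str(design.chromosomes[idx[0]])
        lo, hi = int(design.starts[idx[0]]), int(design.ends[idx[-1]])
        for sid in res.calls:
            overlapping_dup = [
                c for c in res.calls[sid]
                if c.direction is State.DUP and c.overlaps(chrom, lo, hi)
            ]
            assert not overlapping_dup
            if sid in carriers:
                assert any(
                    c.direction is State.DEL and c.overlaps(chrom, lo, hi)
                    for c in res.calls[sid]
                )

    def test_single_carrier_same_with_and_without_stage2(self, panel_design):
        spec = SimulationSpec(design=panel_design, n_samples=8, noise_cv=0.05,
                              seed=21)
        run = simulate_run(spec)
        run = apply_cnv(run, CnvEvent("S4", gene_region(panel_design, "G25A"),
                                      copy_number=1))
        res2 = two_stage_detect(run, dcfg=DetectionConfig(two_stage=True))
        res1 = two_stage_detect(run, dcfg=DetectionConfig(two_stage=False))
        key = lambda calls: [
            (c.chromosome, c.start, c.end, c.direction) for c in calls
        ]
        for sid in run.sample_ids:
            assert key(res1.calls[sid]) == key(res2.calls[sid])

    def test_control_mode_skips_stage2(self, panel_design):
        spec = SimulationSpec(design=panel_design, n_samples=5, noise_cv=0.05,
                              seed=5)
        run = simulate_run(spec)
        ncfg = NormalizationConfig(control_sample_ids=frozenset({"S4", "S5"}))
        res = two_stage_detect(run, ncfg)
        assert res.calls is res.stage1_calls

    def test_z_identity_holds_on_final_nrc(self, panel_design):
        spec = SimulationSpec(design=panel_design, n_samples=6, noise_cv=0.05,
                              seed=2)
        res = two_stage_detect(simulate_run(spec))
        for j in range(6):
            z = z_scores(res.nrc.nrc[:, j])
            finite = np.isfinite(z)
            assert abs(z[finite].mean()) < 1e-9
            assert abs(z[finite].std() - 1.0) < 1e-9


@pytest.mark.parametrize("seed", range(5))
def test_germline_recovery_single_deletion(panel_design, seed):
    """A lone heterozygous deletion carrier is called exactly once with high
    amplicon coverage; non-carriers stay clean over the region."""
    spec = SimulationSpec(design=panel_design, n_samples=16, noise_cv=0.05,
                          seed=100 + seed)
    run = simulate_run(spec)
    region = gene_region(panel_design, "G25B")
    run = apply_cnv(run, CnvEvent("S7", region, copy_number=1))
    res = two_stage_detect(run)
    idx = panel_design.gene_indices("G25B")
    chrom = str(panel_design.chromosomes[idx[0]])
    lo, hi = int(panel_design.starts[idx[0]]), int(panel_design.ends[idx[-1]])
    carrier_calls = [
        c for c in res.calls["S7"]
        if c.direction is State.DEL and c.overlaps(chrom, lo, hi)
    ]
    assert len(carrier_calls) == 1
    covered = len(set(carrier_calls[0].amplicon_ids)
                  & {panel_design.ids[i] for i in idx})
    assert covered >= 0.87 * len(idx)
    for sid in run.sample_ids:
        if sid == "S7":
            continue
        assert not any(c.overlaps(chrom, lo, hi) for c in res.calls[sid])
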