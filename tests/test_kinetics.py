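import itertools

import numpy as np
import pytest

from aggkin.kinetics import (FRAGMENTATION, FUSION, MIRROR_TYPE,
                             MONOMER_ADDITION, MONOMER_LOSS,
                             MONOMERS_TO_OLIGOMER, OLIGOMER_TO_MONOMERS,
                             KineticEvent, align_energy_traces,
                             classify_events, cumulative_size_curves,
                             detect_nucleation_and_reversibility, event_totals,
                             events_for_timeseries, fit_sigmoid, match_clusters,
                             rate_series, replay_events, reversal_fractions,
                             structure_maps)


def fs(*xs):
    return [frozenset(x) for x in xs]


class TestMatchClusters:
    def test_identity_no_events(self):
        groups = fs({0, 1, 2}, {3}, {4})
        comps = match_clusters(groups, groups)
        assert all(c.unchanged for c in comps)
        assert classify_events(groups, groups, 0, 1) == []

    def test_five_to_six_overlap(self):
        before = fs({0, 1, 2, 3, 4}, {5})
        after = fs({0, 1, 2, 3, 4, 5})
        comps = match_clusters(before, after)
        assert len(comps) == 1
        assert len(comps[0].groups_before) == 2

    def test_matches_max_overlap_oracle(self, rng):
        # random reshuffles on <= 8 peptides: the inherited identity equals
        # a brute-force maximum-overlap assignment
        from aggkin.kinetics import lineage_identity
        for _ in range(100):
            n = 8
            labels_a = rng.integers(0, 3, size=n)
            labels_b = rng.integers(0, 3, size=n)
            ga = [frozenset(np.flatnonzero(labels_a == k)) for k in range(3)]
            ga = [g for g in ga if g]
            gb = [frozenset(np.flatnonzero(labels_b == k)) for k in range(3)]
            gb = [g for g in gb if g]
            for comp in match_clusters(ga, gb):
                ident = lineage_identity(comp)
                for g_after, g_before in ident.items():
                    best = max(len(g & g_after) for g in comp.groups_before)
                    assert len(g_before & g_after) == best


class TestClassifyEvents:
    def test_monomer_addition(self):
        ev = classify_events(fs({0, 1, 2, 3, 4}, {5}), fs({0, 1, 2, 3, 4, 5}), 0, 1)
        assert [e.type for e in ev] == [MONOMER_ADDITION]
        assert ev[0].sizes_before == (5, 1)
        assert ev[0].sizes_after == (6,)

    def test_fusion(self):
        ev = classify_events(fs({0, 1, 2}, {3, 4, 5, 6}), fs(set(range(7))), 0, 1)
        assert [e.type for e in ev] == [FUSION]
        assert ev[0].sizes_before == (4, 3)

    def test_monomers_to_oligomer(self):
        ev = classify_events(fs({0}, {1}, {2}), fs({0, 1, 2}), 0, 1)
        assert [e.type for e in ev] == [MONOMERS_TO_OLIGOMER]

    def test_dimer_is_single_monomer_event(self):
        ev = classify_events(fs({0}, {1}), fs({0, 1}), 0, 1)
        assert [e.type for e in ev] == [MONOMER_ADDITION]
        ev = classify_events(fs({0, 1}), fs({0}, {1}), 0, 1)
        assert [e.type for e in ev] == [MONOMER_LOSS]

    def test_compound_two_additions(self):
        ev = classify_events(fs({0, 1, 2}, {3}, {4}), fs({0, 1, 2, 3, 4}), 0, 1)
        assert [e.type for e in ev] == [MONOMER_ADDITION, MONOMER_ADDITION]
        assert all(e.compound for e in ev)

    def test_exchange_decomposes_not_dropped(self):
        before = fs({0, 1, 2}, {3})
        after = fs({0, 1, 3}, {2})
        ev = classify_events(before, after, 0, 1)
        assert len(ev) == 2
        assert sorted(e.type for e in ev) == sorted([MONOMER_ADDITION, MONOMER_LOSS])

    def test_mass_violation_rejected(self):
        with pytest.raises(ValueError):
            KineticEvent(0, 1, FUSION, (2, 3), (6,))

    def test_time_reversal_mirror(self, rng):
        # reversing the transition mirrors the event-type multiset
        for _ in range(100):
            n = 10
            la = rng.integers(0, 4, size=n)
            lb = rng.integers(0, 4, size=n)
            ga = [frozenset(np.flatnonzero(la == k)) for k in range(4)]
            ga = [g for g in ga if g]
            gb = [frozenset(np.flatnonzero(lb == k)) for k in range(4)]
            gb = [g for g in gb if g]
            fwd = classify_events(ga, gb, 0, 1)
            rev = classify_events(gb, ga, 0, 1)
            assert sorted(MIRROR_TYPE[e.type] for e in fwd) == \
                sorted(e.type for e in rev)

    def test_replay_reproduces_histograms(self, rng):
        # random partition walks: replaying classified events reproduces
        # every subsequent size histogram exactly
        for _ in range(20):
            n = 12
            seq = []
            labels = np.arange(n)  # start all monomers (distinct labels)
            for _step in range(15):
                seq.append([frozenset(np.flatnonzero(labels == k))
                            for k in sorted(set(labels))])
                move = rng.random()
                ks = sorted(set(labels))
                if move < 0.5 and len(ks) > 1:  # merge two groups
                    a, b = rng.choice(ks, size=2, replace=False)
                    labels[labels == b] = a
                elif len(ks) >= 1:  # split a random group
                    k = int(rng.choice(ks))
                    members = np.flatnonzero(labels == k)
                    if len(members) >= 2:
                        take = rng.choice(members,
                                          size=int(rng.integers(1, len(members))),
                                          replace=False)
                        labels[take] = labels.max() + 1
            hist = np.zeros(n + 1, dtype=int)
            for g in seq[0]:
                hist[len(g)] += 1
            for a, b in zip(seq, seq[1:]):
                ev = classify_events(a, b, 0, 1)
                for e in ev:
                    for s in e.sizes_before:
                        hist[s] -= 1
                    for s in e.sizes_after:
                        hist[s] += 1
                expect = np.zeros(n + 1, dtype=int)
                for g in b:
                    expect[len(g)] += 1
                assert np.array_equal(hist, expect)
                assert (hist >= 0).all()


class TestRates:
    def _one_addition(self):
        return [KineticEvent(0.0, 5.0, MONOMER_ADDITION, (4, 1), (5,))]

    def test_definition_arithmetic(self):
        rs = rate_series(self._one_addition(), bin_width=5.0, t_start=0.0,
                         t_end=5.0, max_size=8)
        assert rs.rate("c_mono")[0, 5] == pytest.approx(0.2)
        assert rs.rate("d_mono")[0, 4] == pytest.approx(0.2)
        assert rs.rate("d_mono")[0, 1] == pytest.approx(0.2)

    def test_empty_stream(self):
        rs = rate_series([], bin_width=5.0, t_start=0.0, t_end=10.0)
        assert rs.net_counts.sum() == 0

    def test_mass_conservation_scripted(self, rng):
        events = []
        t = 0.0
        for _ in range(200):
            t += float(rng.random())
            kind = rng.integers(4)
            if kind == 0:
                events.append(KineticEvent(t, t, MONOMER_ADDITION, (3, 1), (4,)))
            elif kind == 1:
                events.append(KineticEvent(t, t, MONOMER_LOSS, (4,), (3, 1)))
            elif kind == 2:
                events.append(KineticEvent(t, t, FUSION, (3, 2), (5,)))
            else:
                events.append(KineticEvent(t, t, FRAGMENTATION, (5,), (3, 2)))
        rs = rate_series(events, bin_width=10.0)
        assert np.abs(rs.mass_flux()).max() == 0

    def test_bin_width_below_save_interval(self):
        with pytest.raises(ValueError):
            rate_series([], bin_width=1.0, save_interval=7.5)


class TestEventTotals:
    def test_counting(self):
        events = [KineticEvent(0, 1.0, MONOMER_ADDITION, (2, 1), (3,)),
                  KineticEvent(0, 2.0, MONOMER_ADDITION, (3, 1), (4,)),
                  KineticEvent(0, 3.0, MONOMER_ADDITION, (4, 1), (5,)),
                  KineticEvent(0, 4.0, FUSION, (5, 2), (7,))]
        tot = event_totals(events, bin_width=5.0, t_start=0.0, t_end=5.0)
        assert tot.m_single[0] == 3
        assert tot.m_multi[0] == 1

    def test_gillespie_log_equals_classified(self):
        from aggkin.synthetic_data import gillespie_aggregation, kinetic_preset_config
        trace = gillespie_aggregation(kinetic_preset_config(seed=9, max_events=2000))
        ev = events_for_timeseries(trace.partitions())
        assert len(ev) == len(trace.event_log)
        for got, (t, etype, before, after) in zip(ev, trace.event_log):
            assert got.type == etype
            assert tuple(sorted(got.sizes_before)) == tuple(sorted(before))
            assert tuple(sorted(got.sizes_after)) == tuple(sorted(after))

    def test_empty(self):
        tot = event_totals([], bin_width=5.0, t_start=0.0, t_end=10.0)
        assert tot.m_single.sum() == 0 and tot.m_multi.sum() == 0


class TestCumulativeCurves:
    def test_monotone_growth_steps_ordered(self, growth8):
        _, partitions, _ = growth8
        times, curves, mono = cumulative_size_curves(
            [[sorted(len(g) for g in p) for p in partitions]], max_size=8)
        first_t = {}
        for s, c in curves.items():
            nz = np.flatnonzero(c > 0)
            assert len(nz) > 0
            first_t[s] = times[nz[0]]
            # single-run curve is a step function
            assert set(np.unique(c)) <= {0.0, 1.0}
        steps = [first_t[s] for s in sorted(first_t)]
        assert steps == sorted(steps)

    def test_all_monomer(self):
        run = [[1] * 10 for _ in range(5)]
        times, curves, mono = cumulative_size_curves([run], max_size=4)
        assert all(c.sum() == 0 for c in curves.values())
        assert np.all(mono == 1.0)

    def test_ensemble_recount_oracle(self, rng):
        from aggkin.synthetic_data import gillespie_aggregation, kinetic_preset_config
        runs = [gillespie_aggregation(
            kinetic_preset_config(seed=s, max_events=300)).frame_sizes()
            for s in range(5)]
        n_frames = min(len(r) for r in runs)
        times, curves, mono = cumulative_size_curves(runs, max_size=6)
        for s in (2, 4, 6):
            recount = [np.mean([max(run[i]) >= s for run in runs])
                       for i in range(n_frames)]
            np.testing.assert_allclose(curves[s], recount)


class TestSigmoidFit:
    def test_exact_recovery(self):
        t = np.linspace(0, 100, 200)
        y = 2.0 + 7.0 / (1 + np.exp(-(t - 40.0) / 5.0))
        fit = fit_sigmoid(t, y)
        assert fit.ok
        assert fit.amplitude == pytest.approx(7.0, abs=1e-6)
        assert fit.t0 == pytest.approx(40.0, abs=1e-6)
        assert fit.tau == pytest.approx(5.0, abs=1e-6)
        assert fit.lag_time == pytest.approx(30.0, abs=1e-5)

    def test_constant_flagged(self):
        t = np.linspace(0, 10, 50)
        fit = fit_sigmoid(t, np.ones_like(t))
        assert not fit.ok

    def test_noisy_recovery_median_error(self, rng):
        t = np.linspace(0, 100, 150)
        errs = []
        for _ in range(50):
            y = 1.0 / (1 + np.exp(-(t - 50.0) / 6.0))
            y = y + rng.normal(0, 0.05, size=t.size)
            fit = fit_sigmoid(t, y, min_goodness=0.5)
            if fit.ok:
                errs.append(abs(fit.t0 - 50.0) / 50.0)
        assert np.median(errs) < 0.10


class TestEpisodes:
    def test_monotone_growth_one_episode(self):
        times = np.arange(0, 100, 1.0)
        sizes = np.minimum(times // 5 + 1, 20)
        eps = detect_nucleation_and_reversibility(times, sizes, n_star=5,
                                                  hold_time=3.0,
                                                  dissolve_threshold=2)
        assert len(eps) == 1
        assert not eps[0].reversed

    def test_grow_dissolve_grow(self):
        sizes = [1] * 10 + [8] * 20 + [1] * 20 + [8] * 20
        times = np.arange(len(sizes), dtype=float)
        eps = detect_nucleation_and_reversibility(times, sizes, n_star=5,
                                                  hold_time=5.0,
                                                  dissolve_threshold=2)
        assert len(eps) == 2
        assert eps[0].reversed and not eps[1].reversed

    def test_gillespie_reversal_recount(self):
        from aggkin.synthetic_data import gillespie_aggregation, kinetic_preset_config
        cfg = kinetic_preset_config(seed=4, max_events=4000,
                                    detach_rate=1.2, fragmentation_rate=0.3)
        trace = gillespie_aggregation(cfg)
        sizes = trace.largest_sizes()
        times = trace.snapshot_times
        eps = detect_nucleation_and_reversibility(times, sizes, n_star=5,
                                                  hold_time=0.0,
                                                  dissolve_threshold=2)
        # recount oracle with hold_time 0: nucleation = upcrossing to >= 5,
        # reversal = subsequent downcrossing to <= 2
        state = "wait"
        recount = []
        for s in sizes:
            if state == "wait" and s >= 5:
                recount.append(False)
                state = "up"
            elif state == "up" and s <= 2:
                recount[-1] = True
                state = "wait"
        assert len(eps) == len(recount)
        assert [e.reversed for e in eps] == recount
        stats = reversal_fractions([eps])
        if recount:
            assert stats["episode_fraction"] == pytest.approx(np.mean(recount))


class TestEnergyAlignment:
    def test_identical_traces_zero_sd(self):
        t = np.linspace(0, 30_000, 400)
        e = 200 - 600 / (1 + np.exp(-(t - 15_000) / 800))
        prof = align_energy_traces([(t, e)] * 4, threshold=-80.0)
        assert np.nanmax(prof.sd) == pytest.approx(0.0, abs=1e-9)

    def test_time_shifts_removed(self):
        t = np.linspace(0, 30_000, 3000)
        e = 200 - 600 / (1 + np.exp(-(t - 15_000) / 800))
        traces = [(t + shift, e) for shift in (0.0, 2_000.0, -3_000.0)]
        prof = align_energy_traces(traces, threshold=-80.0)
        core = np.abs(prof.grid) < 4000
        assert np.nanmax(prof.sd[core]) < 1.0

    def test_drop_amplitude_recovered(self, rng):
        t = np.linspace(0, 30_000, 2000)
        traces = []
        for _ in range(5):
            e = 200 - 600 / (1 + np.exp(-(t - 15_000) / 800))
            traces.append((t, e + rng.normal(0, 5.0, t.size)))
        prof = align_energy_traces(traces, threshold=-80.0)
        drop = np.nanmax(prof.mean) - np.nanmin(prof.mean)
        assert drop == pytest.approx(600, abs=30)

    def test_non_crossing_excluded(self):
        t = np.linspace(0, 100, 50)
        good = 100 - 300 / (1 + np.exp(-(t - 50) / 5))
        flat = np.full_like(t, 100.0)
        with pytest.warns(UserWarning):
            prof = align_energy_traces([(t, good), (t, flat)],
                                       threshold=-80.0, window=30.0)
        assert prof.n_traces == 1 and prof.excluded == 1


class TestStructureMaps:
    def test_single_repeated_frame(self):
        maps = structure_maps([10] * 5, [20] * 5, list(range(5)))
        assert maps.density.sum() == pytest.approx(1.0)
        assert (maps.density > 0).sum() == 1

    def test_two_phase_script(self):
        hb = [0] * 10 + [40] * 10
        ct = [5] * 10 + [80] * 10
        times = list(range(20))
        maps = structure_maps(hb, ct, times)
        occupied = np.argwhere(maps.density > 0)
        assert len(occupied) == 2
        # the sheet-phase bin was visited last
        assert np.nanmax(maps.last_visit_time) == 19

    def test_density_normalized(self, rng):
        maps = structure_maps(rng.integers(0, 50, 100), rng.integers(0, 100, 100),
                              np.arange(100.0))
        assert maps.density.sum() == pytest.approx(1.0)
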