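"""Sliding-window caller: window classification, segment filtering against a
brute-force oracle, breakpoint intervals and QC."""

from itertools import groupby

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copmap import sim as msim
from copmap.caller import (
    ChromWindows,
    UninformativeSampleError,
    call_crossovers,
    call_sample,
    genotype_windows,
    qc_sample,
    segment_and_filter,
)
from copmap.io import HET, HOM_A, SampleCounts
from copmap.layout import GenomeLayout, MarkerMap

U = "UNKNOWN"


def windows_from_states(states, window=30_000, step=15_000):
    """A ChromWindows carrying given states with dummy marker evidence."""
    n = len(states)
    starts = np.arange(n, dtype=np.int64) * step
    return ChromWindows(
        chromosome="c",
        starts=starts,
        ends=starts + window,
        states=np.array(states, dtype=object),
        reads_A=np.zeros(n),
        reads_B=np.zeros(n),
        n_markers=np.zeros(n),
        marker_pos=np.array([], dtype=np.int64),
        marker_reads_A=np.array([], dtype=np.int64),
        marker_reads_B=np.array([], dtype=np.int64),
    )


def oracle_filter(states, min_internal=5, min_terminal=2):
    """Independent reference implementation of the support filter.

    Works on (state, count) run tuples and re-derives the runs from scratch
    after every removal, applying the prescribed order: terminal segments
    first (left before right), then the weakest internal segment (leftmost
    on ties), until stable.
    """
    runs = [(s, len(list(g))) for s, g in groupby(states) if s != U]
    # merge same-state runs separated by removed UNKNOWNs
    def remerge(rs):
        out = []
        for s, n in rs:
            if out and out[-1][0] == s:
                out[-1] = (s, out[-1][1] + n)
            else:
                out.append((s, n))
        return out

    runs = remerge(runs)
    if not runs:
        return None
    while len(runs) > 1:
        if runs[0][1] < min_terminal:
            runs = remerge(runs[1:])
        elif runs[-1][1] < min_terminal:
            runs = remerge(runs[:-1])
        else:
            bad = [(n, i) for i, (s, n) in enumerate(runs)
                   if 0 < i < len(runs) - 1 and n < min_internal]
            if not bad:
                break
            _, i = min(bad)
            runs = remerge(runs[:i] + runs[i + 1:])
    return runs


class TestWindowClassification:
    def _sample(self, reads):
        counts = pd.DataFrame(
            {
                "chrom": ["c"] * len(reads),
                "pos": [5_000 + 1_000 * i for i in range(len(reads))],
                "reads_A": [r[0] for r in reads],
                "reads_B": [r[1] for r in reads],
            }
        )
        return SampleCounts("s", counts)

    def _windows(self, reads, **kw):
        layout = GenomeLayout([("c", 60_000)])
        markers = MarkerMap({"c": np.array([5_000 + 1_000 * i for i in range(len(reads))])})
        return genotype_windows(self._sample(reads), layout, markers,
                                min_reads=3, **kw)["c"]

    def test_clear_tester_evidence_is_hom(self):
        assert self._windows([(6, 0)]).states[0] == HOM_A

    def test_balanced_reads_are_het(self):
        assert self._windows([(3, 3)]).states[0] == HET

    def test_sparse_window_is_unknown(self):
        assert self._windows([(1, 0)]).states[0] == U

    def test_baf_tie_classifies_het(self):
        # 4 A + 1 B = BAF 0.2, equal to the threshold
        assert self._windows([(4, 1)]).states[0] == HET


class TestSegmentFilter:
    @pytest.mark.parametrize(
        "states, expected",
        [
            # sub-threshold internal run vanishes with both its transitions
            (["A"] * 10 + ["B"] * 4 + ["A"] * 10, [("A", 20)]),
            # sub-threshold terminal run dropped
            (["B"] * 1 + ["A"] * 20, [("A", 20)]),
            # exactly at the internal threshold: both crossovers retained
            (["A"] * 10 + ["B"] * 5 + ["A"] * 10, [("A", 10), ("B", 5), ("A", 10)]),
            # UNKNOWN runs absorbed between same-state segments
            (["A"] * 3 + [U] * 4 + ["A"] * 3, [("A", 6)]),
        ],
    )
    def test_frozen_examples(self, states, expected):
        hom = [HOM_A if s == "A" else (HET if s == "B" else U) for s in states]
        segs = segment_and_filter(windows_from_states(hom))
        got = [("A" if s.state == HOM_A else "B", s.support) for s in segs]
        assert got == expected

    def test_all_unknown_raises(self):
        with pytest.raises(UninformativeSampleError):
            segment_and_filter(windows_from_states([U] * 10))

    @given(st.lists(st.sampled_from(["A", "B", U]), min_size=1, max_size=30))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, states):
        expected = oracle_filter(states)
        hom = [HOM_A if s == "A" else (HET if s == "B" else U) for s in states]
        if expected is None:
            with pytest.raises(UninformativeSampleError):
                segment_and_filter(windows_from_states(hom))
            return
        segs = segment_and_filter(windows_from_states(hom))
        got = [("A" if s.state == HOM_A else "B", s.support) for s in segs]
        assert got == expected

    @given(st.lists(st.sampled_from(["A", "B", U]), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_filtering_is_idempotent_and_alternating(self, states):
        hom = [HOM_A if s == "A" else (HET if s == "B" else U) for s in states]
        try:
            segs = segment_and_filter(windows_from_states(hom))
        except UninformativeSampleError:
            return
        # alternating states
        for a, b in zip(segs, segs[1:]):
            assert a.state != b.state
        # surviving segments respect the thresholds (unless only one remains)
        if len(segs) > 1:
            assert segs[0].support >= 2 and segs[-1].support >= 2
            for s in segs[1:-1]:
                assert s.support >= 5
        # re-filtering the surviving runs changes nothing
        rerun = []
        for s in segs:
            rerun += [s.state] * s.support
        segs2 = segment_and_filter(windows_from_states(rerun))
        assert [(s.state, s.support) for s in segs2] == [
            (s.state, s.support) for s in segs
        ]


class TestCalling:
    def _simulate_one(self, x, rng, depth=5.0, density=200.0, error=0.0):
        layout = GenomeLayout([("chr1", 20_000_000)])
        markers = msim.make_marker_map(layout, density, rng)
        g = msim.GameteGenotype(
            {"chr1": np.array(x, dtype=float)}, {"chr1": "A"},
            {"chr1": np.repeat("I", len(x))},
        )
        s = msim.sequence_gamete(g, markers, depth, error, rng, sample_id="s")
        return s, layout, markers

    def test_single_segment_yields_no_calls(self):
        cw = windows_from_states([HOM_A] * 12)
        segs = segment_and_filter(cw)
        assert call_crossovers(segs, cw) == []

    def test_isolated_crossover_called_and_contained(self, rng):
        s, layout, markers = self._simulate_one([9_000_000], rng)
        calls = call_sample(s, layout, markers)
        assert len(calls) == 1
        assert calls[0].left_bound <= 9_000_000 <= calls[0].right_bound
        assert calls[0].left_state == HOM_A and calls[0].right_state == HET

    def test_close_double_crossover_collapses(self, rng):
        # two truth COs 40 kb apart: at most 4 windows can ever support the
        # middle segment, below the 5-window (90 kb) requirement
        s, layout, markers = self._simulate_one([9_000_000, 9_040_000], rng,
                                                depth=10.0, density=500.0)
        calls = call_sample(s, layout, markers)
        assert len(calls) == 0

    def test_terminal_crossover_inside_blind_spot_dropped(self, rng):
        s, layout, markers = self._simulate_one([20_000], rng,
                                                depth=10.0, density=500.0)
        calls = call_sample(s, layout, markers)
        assert len(calls) == 0

    def test_marker_row_order_irrelevant(self, rng):
        s, layout, markers = self._simulate_one([9_000_000], rng)
        shuffled = SampleCounts(
            s.sample_id,
            s.counts.sample(frac=1.0, random_state=1).reset_index(drop=True),
        )
        a = call_sample(s, layout, markers)
        b = call_sample(shuffled, layout, markers)
        assert [(c.left_bound, c.right_bound) for c in a] == [
            (c.left_bound, c.right_bound) for c in b
        ]


class TestQC:
    def test_zero_read_sample_flagged_low_coverage(self, layout):
        counts = pd.DataFrame({"chrom": [], "pos": [], "reads_A": [], "reads_B": []})
        report = qc_sample(SampleCounts("s", counts), [], layout)
        assert "low_coverage" in report.flags

    def test_clean_bc1_sample_passes(self, layout, rng):
        cfg = msim.SimConfig(layout, female=msim.PathwayParams(class1_mean=1.12),
                             seed=5)
        samples, markers, _ = msim.simulate_counts(cfg, 1, "female")
        calls = call_sample(samples[0], layout, markers)
        assert qc_sample(samples[0], calls, layout).passed

    def test_diploid_f1_profile_flagged_as_contamination(self, layout, rng):
        # BAF ~0.5 genome-wide with no homozygous stretch: an F1, not a BC1
        markers = msim.make_marker_map(layout, 25.0, rng)
        frames = []
        for chrom, pos in markers.positions.items():
            n = rng.poisson(2.0, size=len(pos))
            b = rng.binomial(n, 0.5)
            frames.append(pd.DataFrame(
                {"chrom": chrom, "pos": pos, "reads_A": n - b, "reads_B": b}
            ))
        s = SampleCounts("f1", pd.concat(frames, ignore_index=True))
        report = qc_sample(s, [], layout)
        assert "contamination_suspect" in report.flags
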