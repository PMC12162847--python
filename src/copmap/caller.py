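"""Sliding-window crossover caller for shallow-sequenced BC1 gametes.

Each chromosome is tiled by 30-kb windows advancing in 15-kb steps.  A
window pools the reads of the markers it contains and is classified HOM_A,
HET or UNKNOWN; runs of identically classified informative windows form
segments; sub-threshold segments are removed (a double crossover needs at
least five supporting windows, 90 kb; a terminal segment at least two,
45 kb) and the surviving alternating segments define the crossovers.  By
construction the caller therefore misses double crossovers closer than
90 kb and terminal crossovers within 45 kb of a chromosome end.

UNKNOWN windows (insufficient pooled reads, e.g. marker deserts) are
absorbed: they never break a segment, and a crossover whose breakpoint
falls in an uninformative stretch simply gets a wider uncertainty interval.
Support thresholds count informative windows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from copmap.io import HET, HOM_A, CrossoverCall, SampleCounts
from copmap.layout import GenomeLayout, MarkerMap
from copmap.tracks import window_starts

UNKNOWN_STATE = "UNKNOWN"

DEFAULT_WINDOW = 30_000
DEFAULT_STEP = 15_000
MIN_INTERNAL_WINDOWS = 5
MIN_TERMINAL_WINDOWS = 2


class UninformativeSampleError(ValueError):
    """Raised when no window on a chromosome carries enough reads to call."""


@dataclass
class ChromWindows:
    """Window genotypes of one chromosome of one sample."""

    chromosome: str
    starts: np.ndarray
    ends: np.ndarray
    states: np.ndarray          # array of HOM_A / HET / UNKNOWN
    reads_A: np.ndarray
    reads_B: np.ndarray
    n_markers: np.ndarray
    marker_pos: np.ndarray        # all marker positions on this chromosome
    marker_reads_A: np.ndarray    # per-marker reads supporting each allele
    marker_reads_B: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class Segment:
    """A maximal run of identically classified informative windows."""

    chromosome: str
    state: str
    window_indices: list[int]   # indices into the window arrays, ascending

    @property
    def support(self) -> int:
        return len(self.window_indices)

    @property
    def first(self) -> int:
        return self.window_indices[0]

    @property
    def last(self) -> int:
        return self.window_indices[-1]


def genotype_windows(
    sample: SampleCounts,
    layout: GenomeLayout,
    markers: MarkerMap,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_reads: int = 4,
    het_baf_min: float = 0.2,
) -> dict[str, ChromWindows]:
    """Classify sliding windows from pooled marker allele counts.

    A window is UNKNOWN when its pooled read count is below ``min_reads``;
    otherwise HET when the B-allele fraction is >= ``het_baf_min`` (ties
    classify as HET), else HOM_A.
    """
    if step > window:
        raise ValueError("step must not exceed window size")
    out = {}
    for chrom, length in layout.chromosomes:
        pos = markers.positions.get(chrom, np.array([], dtype=np.int64))
        sub = sample.per_chromosome(chrom)
        reads_a = np.zeros(len(pos), dtype=np.int64)
        reads_b = np.zeros(len(pos), dtype=np.int64)
        if len(sub):
            idx = np.searchsorted(pos, sub["pos"].to_numpy())
            reads_a[idx] = sub["reads_A"].to_numpy()
            reads_b[idx] = sub["reads_B"].to_numpy()
        starts = window_starts(length, window, step)
        ends = np.minimum(starts + window, length)
        csum_a = np.concatenate([[0], np.cumsum(reads_a)])
        csum_b = np.concatenate([[0], np.cumsum(reads_b)])
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, ends)
        win_a = csum_a[hi] - csum_a[lo]
        win_b = csum_b[hi] - csum_b[lo]
        total = win_a + win_b
        with np.errstate(invalid="ignore", divide="ignore"):
            baf = np.where(total > 0, win_b / np.maximum(total, 1), 0.0)
        states = np.where(
            total < min_reads, UNKNOWN_STATE, np.where(baf >= het_baf_min, HET, HOM_A)
        )
        out[chrom] = ChromWindows(
            chromosome=chrom,
            starts=starts,
            ends=ends,
            states=states,
            reads_A=win_a,
            reads_B=win_b,
            n_markers=hi - lo,
            marker_pos=pos,
            marker_reads_A=reads_a,
            marker_reads_B=reads_b,
        )
    return out


def _runs(states: np.ndarray, chrom: str) -> list[Segment]:
    informative = np.flatnonzero(states != UNKNOWN_STATE)
    segments: list[Segment] = []
    for i in informative:
        state = states[i]
        if segments and segments[-1].state == state:
            segments[-1].window_indices.append(int(i))
        else:
            segments.append(Segment(chrom, state, [int(i)]))
    return segments


def _merge_adjacent(segments: list[Segment]) -> list[Segment]:
    merged: list[Segment] = []
    for seg in segments:
        if merged and merged[-1].state == seg.state:
            merged[-1].window_indices.extend(seg.window_indices)
        else:
            merged.append(seg)
    return merged


def segment_and_filter(
    windows: ChromWindows,
    min_internal: int = MIN_INTERNAL_WINDOWS,
    min_terminal: int = MIN_TERMINAL_WINDOWS,
) -> list[Segment]:
    """Segment one chromosome and apply the support filters to a fixpoint.

    Removal order is deterministic: sub-threshold terminal segments first
    (leftmost first), then the weakest sub-threshold internal segment
    (ties broken leftmost); after each removal adjacent same-state segments
    re-merge, and the procedure iterates until stable.  A single surviving
    segment is never removed.
    """
    segments = _runs(np.asarray(windows.states), windows.chromosome)
    if not segments:
        raise UninformativeSampleError(
            f"uninformative sample: no informative window on {windows.chromosome}"
        )
    while True:
        segments = _merge_adjacent(segments)
        if len(segments) == 1:
            break
        # terminal rule
        if segments[0].support < min_terminal:
            segments.pop(0)
            continue
        if segments[-1].support < min_terminal:
            segments.pop()
            continue
        # internal rule: drop the weakest sub-threshold internal segment
        internal = [
            (seg.support, i)
            for i, seg in enumerate(segments[1:-1], start=1)
            if seg.support < min_internal
        ]
        if not internal:
            break
        _, i = min(internal)
        segments.pop(i)
    return segments


def _refine_breakpoint(
    windows: ChromWindows,
    left: Segment,
    right: Segment,
    reads_a: np.ndarray,
    reads_b: np.ndarray,
    error_rate: float,
    flank_windows: int = 5,
    support_loglik: float = 6.9,
) -> tuple[int, int] | None:
    """Marker-level likelihood placement of one breakpoint.

    Window classification can be fooled near the transition (a handful of
    reads at ~2x depth), so the breakpoint is re-placed on the raw marker
    counts spanning the last ``flank_windows`` informative windows of the
    left segment and the first of the right.  Reads are modelled Binomial:
    B-allele probability ``error_rate`` under HOM_A, 0.5 under HET.  The
    reported interval is a likelihood support interval: the contiguous run
    of inter-marker gaps whose split log-likelihood is within
    ``support_loglik`` of the optimum (default ln 1000) — at shallow depth
    a run of markers is often genuinely ambiguous, and a single best gap
    would be overconfident.
    """
    pos = windows.marker_pos
    span_lo = windows.starts[left.window_indices[max(0, left.support - flank_windows)]]
    span_hi = windows.ends[right.window_indices[min(flank_windows, right.support) - 1]]
    sel = (pos >= span_lo) & (pos < span_hi) & (reads_a + reads_b > 0)
    if sel.sum() < 2:
        return None
    p = pos[sel]
    a = reads_a[sel].astype(float)
    b = reads_b[sel].astype(float)
    eps = max(error_rate, 1e-6)
    ll_hom = a * np.log1p(-eps) + b * np.log(eps)
    ll_het = (a + b) * np.log(0.5)
    ll_left = ll_hom if left.state == HOM_A else ll_het
    ll_right = ll_het if left.state == HOM_A else ll_hom
    # score(j) = sum_{i<=j} ll_left[i] + sum_{i>j} ll_right[i], j = 0..m-2
    prefix = np.cumsum(ll_left)
    suffix = np.cumsum(ll_right[::-1])[::-1]
    score = prefix[:-1] + suffix[1:]
    jmax = int(np.argmax(score))
    good = score >= score[jmax] - support_loglik
    j_lo = jmax
    while j_lo > 0 and good[j_lo - 1]:
        j_lo -= 1
    j_hi = jmax
    while j_hi < len(score) - 1 and good[j_hi + 1]:
        j_hi += 1
    return int(p[j_lo]), int(p[j_hi + 1])


def _marker_loglik(windows: ChromWindows, error_rate: float) -> tuple[np.ndarray, np.ndarray]:
    eps = max(error_rate, 1e-6)
    a = windows.marker_reads_A.astype(float)
    b = windows.marker_reads_B.astype(float)
    ll_hom = a * np.log1p(-eps) + b * np.log(eps)
    ll_het = (a + b) * np.log(0.5)
    return ll_hom, ll_het


def audit_segments(
    segments: list[Segment],
    windows: ChromWindows,
    error_rate: float = 0.01,
    min_loglik: float = 6.9,
) -> list[Segment]:
    """Confirm each segment against the raw marker counts in its span.

    Window-level support can be assembled by chance from a few
    read-starved marker clusters (e.g. heterozygous markers that sampled
    only tester-allele reads), but such spans also contain sub-threshold
    markers contradicting the segment state.  Each segment's log-likelihood
    ratio (its state vs the flanking state) summed over every read-covered
    marker in its window span must reach ``min_loglik``; the weakest
    failing segment is removed, neighbors re-merge, and the audit repeats.
    """
    ll_hom, ll_het = _marker_loglik(windows, error_rate)
    pos = windows.marker_pos

    def lr(seg: Segment) -> float:
        lo = windows.starts[seg.first]
        hi = windows.ends[seg.last]
        sel = (pos >= lo) & (pos < hi)
        diff = ll_hom[sel] - ll_het[sel]
        return float(diff.sum()) if seg.state == HOM_A else float(-diff.sum())

    segments = list(segments)
    while len(segments) > 1:
        scores = [lr(s) for s in segments]
        worst = int(np.argmin(scores))
        if scores[worst] >= min_loglik:
            break
        segments.pop(worst)
        segments = _merge_adjacent(segments)
    return segments


def call_crossovers(
    segments: list[Segment],
    windows: ChromWindows,
    error_rate: float = 0.01,
) -> list[CrossoverCall]:
    """One crossover per adjacent segment pair.

    The breakpoint interval runs between the two consecutive read-covered
    markers flanking the maximum-likelihood transition (see
    :func:`_refine_breakpoint`); where marker evidence is too thin the
    boundary windows themselves bound the interval.  Intervals widen
    naturally across marker deserts.
    """
    calls = []
    reads_a = windows.marker_reads_A
    reads_b = windows.marker_reads_B
    for left, right in zip(segments, segments[1:]):
        refined = _refine_breakpoint(windows, left, right, reads_a, reads_b, error_rate)
        if refined is not None:
            lb, rb = refined
        else:  # no usable marker evidence: span the boundary windows
            lb = int(windows.starts[left.last])
            rb = int(windows.ends[right.first])
        calls.append(
            CrossoverCall(
                sample_id="",
                chromosome=windows.chromosome,
                left_bound=lb,
                right_bound=rb,
                left_state=left.state,
                right_state=right.state,
                n_support_left=left.support,
                n_support_right=right.support,
            )
        )
    return calls


def call_sample(
    sample: SampleCounts,
    layout: GenomeLayout,
    markers: MarkerMap,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_reads: int = 4,
    het_baf_min: float = 0.2,
    min_internal: int = MIN_INTERNAL_WINDOWS,
    min_terminal: int = MIN_TERMINAL_WINDOWS,
    error_rate: float = 0.01,
    audit_min_loglik: float = 6.9,
) -> list[CrossoverCall]:
    """Run the full caller on one sample; chromosomes with no informative
    window yield no calls (the QC step flags such samples)."""
    wins = genotype_windows(sample, layout, markers, window, step, min_reads, het_baf_min)
    calls: list[CrossoverCall] = []
    n_informative_chroms = 0
    for chrom in layout.names:
        cw = wins[chrom]
        try:
            segments = segment_and_filter(cw, min_internal, min_terminal)
        except UninformativeSampleError:
            continue
        n_informative_chroms += 1
        segments = audit_segments(segments, cw, error_rate, audit_min_loglik)
        for call in call_crossovers(segments, cw, error_rate):
            call.sample_id = sample.sample_id
            calls.append(call)
    if n_informative_chroms == 0:
        raise UninformativeSampleError(
            f"uninformative sample: {sample.sample_id} has no callable chromosome"
        )
    return calls


@dataclass
class QCReport:
    sample_id: str
    flags: list[str] = field(default_factory=list)
    metrics: dict[str, float] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return not self.flags


def qc_sample(
    sample: SampleCounts,
    calls: list[CrossoverCall],
    layout: GenomeLayout,
    min_reads_per_mb: float = 10.0,
    baf_band: tuple[float, float] = (0.10, 0.40),
) -> QCReport:
    """Flag low-coverage and contamination-suspect samples.

    A clean BC1 sample has a genome-wide B-allele fraction around 0.25
    (roughly half the genome heterozygous at BAF 0.5, half homozygous
    tester at ~0).  A diploid F1 contaminant sits at ~0.5 genome-wide and a
    pure tester at ~0, both outside ``baf_band``.
    """
    report = QCReport(sample.sample_id)
    total_a = float(sample.counts["reads_A"].sum())
    total_b = float(sample.counts["reads_B"].sum())
    total = total_a + total_b
    density = total / (layout.total_length / 1e6)
    report.metrics["reads_per_mb"] = density
    if density < min_reads_per_mb:
        report.flags.append("low_coverage")
        return report
    baf = total_b / total
    report.metrics["genome_baf"] = baf
    if not (baf_band[0] <= baf <= baf_band[1]):
        report.flags.append("contamination_suspect")
    report.metrics["n_calls"] = len(calls)
    return report
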