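"""Windowed crossover landscapes, CO_P map merging, zones and NRZ audit.

A landscape assigns each crossover to every sliding window containing its
breakpoint-interval midpoint and reports crossovers per gamete per window.
Normalizations: *per-chromosome relative* (each chromosome's values sum to
1 — the proportion of that chromosome's crossovers falling in a window) and
*per-genome relative* (values divided by the genome-wide mean, so the track
averages to 1).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from copmap.io import PopulationCalls
from copmap.layout import GenomeLayout
from copmap.tracks import (
    PER_CHROM_RELATIVE,
    PER_GAMETE,
    PER_GENOME_RELATIVE,
    WindowedTrack,
    window_starts,
)


@dataclass
class Zone:
    chromosome: str
    start: int
    end: int
    supporting_genotypes: list[str]


@dataclass
class ZoneSet:
    kind: str  # "hot" or "cold"
    zones: list[Zone]

    def __len__(self) -> int:
        return len(self.zones)


def _count_midpoints(midpoints: np.ndarray, starts: np.ndarray,
                     window: int, length: int) -> np.ndarray:
    """Number of midpoints falling in each (possibly overlapping) window."""
    mids = np.sort(midpoints)
    ends = np.minimum(starts + window, length)
    return (np.searchsorted(mids, ends, side="left")
            - np.searchsorted(mids, starts, side="left")).astype(float)


def co_landscape(pop: PopulationCalls, layout: GenomeLayout,
                 window: int = 1_000_000, step: int = 50_000) -> WindowedTrack:
    """Per-gamete crossover rate in sliding windows (midpoint assignment)."""
    starts = {}
    values = {}
    for chrom, length in layout.chromosomes:
        s = window_starts(length, window, step)
        counts = _count_midpoints(pop.midpoints(chrom), s, window, length)
        starts[chrom] = s
        values[chrom] = counts / pop.n_gametes
    return WindowedTrack(window, step, starts, values, PER_GAMETE,
                         meta={"n_gametes": pop.n_gametes})


def normalize_per_chromosome(track: WindowedTrack) -> WindowedTrack:
    """Divide each chromosome's values by their sum (relative frequency).

    All-zero chromosomes stay all-zero, with a warning.
    """
    values = {}
    for chrom, v in track.values.items():
        total = v.sum()
        if total <= 0:
            warnings.warn(f"{chrom}: all-zero track, left unnormalized", stacklevel=2)
            values[chrom] = v.copy()
        else:
            values[chrom] = v / total
    return track.copy_with(values, PER_CHROM_RELATIVE)


def normalize_per_genome(track: WindowedTrack) -> WindowedTrack:
    """Divide all values by the genome-wide mean so the track averages to 1."""
    flat = track.flat_values()
    mean = flat.mean() if len(flat) else 0.0
    if mean <= 0:
        raise ValueError("cannot normalize an all-zero track per genome")
    return track.copy_with({c: v / mean for c, v in track.values.items()},
                           PER_GENOME_RELATIVE)


def merge_cop(pops: list[PopulationCalls], layout: GenomeLayout,
              window: int = 300_000, step: int = 50_000,
              per_genome_relative: bool = False) -> WindowedTrack:
    """Crossover-Potential map: pooled crossovers over pooled gametes.

    Merging hyper-recombinant populations reveals the shared landscape of
    eligible recombination precursors; the per-gamete rate uses the summed
    gamete count as denominator, so merging a population with itself leaves
    the rate unchanged.
    """
    if not pops:
        raise ValueError("need at least one population to merge")
    n_total = sum(p.n_gametes for p in pops)
    starts = {}
    values = {}
    for chrom, length in layout.chromosomes:
        s = window_starts(length, window, step)
        mids = np.concatenate([p.midpoints(chrom) for p in pops]) if pops else np.array([])
        counts = _count_midpoints(mids, s, window, length)
        starts[chrom] = s
        values[chrom] = counts / n_total
    track = WindowedTrack(window, step, starts, values, PER_GAMETE,
                          meta={"n_gametes": n_total})
    return normalize_per_genome(track) if per_genome_relative else track


def fold_change_track(mutant: WindowedTrack, wt: WindowedTrack) -> WindowedTrack:
    """Per-window mutant/wild-type rate ratio.

    Wild-type zero windows get a pseudocount of half the smallest nonzero
    wild-type value, so regions devoid of wild-type crossovers (where mutant
    increases can exceed 100-fold) stay finite.
    """
    if not mutant.same_windowing(wt):
        raise ValueError("fold change requires identical windowing")
    wt_flat = wt.flat_values()
    nonzero = wt_flat[wt_flat > 0]
    if len(nonzero) == 0:
        raise ValueError("wild-type track is all zero")
    pseudo = nonzero.min() / 2.0
    values = {
        chrom: mutant.values[chrom] / np.maximum(wt.values[chrom], pseudo)
        for chrom in mutant.starts
    }
    return mutant.copy_with(values, mutant.normalization)


def call_zones(
    fold_tracks: dict[str, WindowedTrack],
    anchor_genotype: str,
    kind: str = "hot",
    min_other: int = 3,
    hot_mult: float = 2.0,
    cold_mult: float = 0.5,
    layout: GenomeLayout | None = None,
) -> ZoneSet:
    """Hot/cold zones of the crossover burst, shared across genotypes.

    A window supports "hot" in a genotype when its fold change is at least
    ``hot_mult`` times that genotype's genome-wide median fold change
    ("cold": at most ``cold_mult`` times).  Zones are maximal runs of
    windows supported by the anchor genotype and at least ``min_other``
    other genotypes; overlapping qualifying windows merge into intervals.
    """
    if anchor_genotype not in fold_tracks:
        raise ValueError(f"anchor genotype {anchor_genotype!r} missing")
    anchor = fold_tracks[anchor_genotype]
    for name, t in fold_tracks.items():
        if not t.same_windowing(anchor):
            raise ValueError(f"track {name!r} has mismatched windowing")

    supports = {}
    for name, t in fold_tracks.items():
        median = float(np.median(t.flat_values()))
        supports[name] = {
            chrom: (v >= hot_mult * median) if kind == "hot" else (v <= cold_mult * median)
            for chrom, v in t.values.items()
        }
    zones = []
    others = [n for n in fold_tracks if n != anchor_genotype]
    for chrom in anchor.starts:
        qual = supports[anchor_genotype][chrom].copy()
        n_other = np.zeros(len(qual), dtype=int)
        for name in others:
            n_other += supports[name][chrom].astype(int)
        qual &= n_other >= min_other
        if not qual.any():
            continue
        s = anchor.starts[chrom]
        length = layout.length(chrom) if layout is not None else s[-1] + anchor.window_size
        ends = np.minimum(s + anchor.window_size, length)
        # merge overlapping/adjacent qualifying windows into intervals
        idx = np.flatnonzero(qual)
        run_start = idx[0]
        prev = idx[0]
        for i in list(idx[1:]) + [None]:
            if i is not None and s[i] <= ends[prev]:
                prev = i
                continue
            support = sorted(
                name for name in fold_tracks
                if supports[name][chrom][run_start:prev + 1].any()
            )
            zones.append(Zone(chrom, int(s[run_start]), int(ends[prev]), support))
            if i is not None:
                run_start = prev = i
    return ZoneSet(kind, zones)


def nrz_audit(pops: list[PopulationCalls], layout: GenomeLayout) -> pd.DataFrame:
    """Count crossovers falling wholly inside Non-Recombining Zones.

    A call is "inside" only when its entire breakpoint interval lies within
    the NRZ; intervals straddling an NRZ boundary are not counted.
    """
    rows = []
    for pop in pops:
        inside = 0
        for call in pop.calls:
            nrz = layout.nrz.get(call.chromosome)
            if nrz and nrz[0] <= call.left_bound and call.right_bound <= nrz[1]:
                inside += 1
        rows.append(
            {
                "genotype": pop.genotype_label,
                "sex": pop.sex,
                "nrz_co_count": inside,
                "total_co_count": len(pop.calls),
            }
        )
    return pd.DataFrame(rows)


def compare_tracks(a: WindowedTrack, b: WindowedTrack) -> float:
    """Spearman rank correlation over paired window values."""
    if not a.same_windowing(b):
        raise ValueError("tracks have mismatched windowing")
    x = a.flat_values()
    y = b.flat_values()
    ok = np.isfinite(x) & np.isfinite(y)
    r = stats.spearmanr(x[ok], y[ok]).statistic
    return float(r)


def write_zones_bed(zoneset: ZoneSet, path) -> None:
    """Zones as BED (0-based half-open, the BED convention)."""
    with open(path, "w") as fh:
        for z in zoneset.zones:
            name = f"{zoneset.kind}:{','.join(z.supporting_genotypes)}"
            fh.write(f"{z.chromosome}\t{z.start}\t{z.end}\t{name}\n")
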