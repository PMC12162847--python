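"""Whole-chromosome aneuploidy screening from windowed sequencing depth.

The genome is cut into non-overlapping 100-kb windows and every unordered
pair of chromosomes is compared by a two-sided Mann-Whitney rank-sum test on
their window depths, with Benjamini-Hochberg adjustment across pairs within
the sample.  A pair is flagged aneuploid when the median-depth fold change
(larger over smaller) exceeds 1.2 AND the adjusted p value is below 1e-20.
A trisomic chromosome in a BC1 plant carries three copies instead of two,
i.e. a 1.5x depth shift, comfortably above the 1.2 bar.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from copmap.layout import GenomeLayout

EUPLOID = "euploid"
GAIN = "gain"
LOSS = "loss"
AMBIGUOUS = "ambiguous"


@dataclass
class DepthProfile:
    """Per-chromosome window depths over non-overlapping windows."""

    sample_id: str
    window: int
    depths: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        for chrom, d in self.depths.items():
            d = np.asarray(d, dtype=float)
            if np.any(d < 0):
                raise ValueError(f"{chrom}: negative depths")
            self.depths[chrom] = d

    def medians(self) -> dict[str, float]:
        return {c: float(np.median(d)) for c, d in self.depths.items()}


@dataclass
class AneuploidyReport:
    sample_id: str
    pairs: pd.DataFrame  # chrom_a, chrom_b, fold_change, fold_change_mean, p_raw, p_adj, flagged
    verdicts: dict[str, str]

    @property
    def is_aneuploid(self) -> bool:
        return any(v != EUPLOID for v in self.verdicts.values())


def depth_windows(source, layout: GenomeLayout, window: int = 100_000) -> DepthProfile:
    """Build a DepthProfile from per-marker allele counts.

    ``source`` is a SampleCounts-like object (``sample_id``, ``counts`` with
    columns chrom/pos/reads_A/reads_B).  Window depth is the summed read
    count of the markers it contains — a marker-restricted proxy for
    coverage; whole-genome depth tables can be ingested directly with
    :func:`read_depth_table`.
    """
    depths = {}
    df = source.counts
    total = df["reads_A"].to_numpy() + df["reads_B"].to_numpy()
    for chrom, length in layout.chromosomes:
        starts = np.arange(0, length, window, dtype=np.int64)
        mask = (df["chrom"] == chrom).to_numpy()
        pos = df["pos"].to_numpy()[mask].astype(np.int64)
        reads = total[mask].astype(float)
        idx = pos // window
        out = np.zeros(len(starts), dtype=float)
        np.add.at(out, idx, reads)
        depths[chrom] = out
    return DepthProfile(source.sample_id, window, depths)


def read_depth_table(path, sample_id: str | None = None, window: int | None = None) -> DepthProfile:
    """Read a per-window depth TSV with columns chrom, start (1-based), depth."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if window is None:
        starts = np.sort(df[df["chrom"] == df["chrom"].iloc[0]]["start"].to_numpy())
        window = int(starts[1] - starts[0]) if len(starts) > 1 else 100_000
    depths = {
        str(chrom): sub.sort_values("start")["depth"].to_numpy(dtype=float)
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    return DepthProfile(sample_id or "sample", window, depths)


def screen_sample(
    profile: DepthProfile,
    fc_min: float = 1.2,
    p_max: float = 1e-20,
    use_adjusted: bool = True,
) -> AneuploidyReport:
    """Pairwise chromosome depth comparison for one sample.

    Fold change is computed on median window depth (robust to local CNV and
    coverage spikes); the mean-based fold change is also reported.  The p
    threshold applies to BH-adjusted p values by default.
    """
    chroms = list(profile.depths)
    if len(chroms) < 2:
        raise ValueError("need at least two chromosomes to screen")
    rows = []
    for a, b in combinations(chroms, 2):
        da, db = profile.depths[a], profile.depths[b]
        med_a, med_b = np.median(da), np.median(db)
        mean_a, mean_b = np.mean(da), np.mean(db)
        lo = min(med_a, med_b)
        fc = np.inf if lo == 0 and max(med_a, med_b) > 0 else (
            1.0 if lo == 0 else max(med_a, med_b) / lo
        )
        lo_m = min(mean_a, mean_b)
        fc_mean = np.inf if lo_m == 0 and max(mean_a, mean_b) > 0 else (
            1.0 if lo_m == 0 else max(mean_a, mean_b) / lo_m
        )
        p = stats.mannwhitneyu(da, db, alternative="two-sided").pvalue
        rows.append(
            {
                "chrom_a": a,
                "chrom_b": b,
                "fold_change": fc,
                "fold_change_mean": fc_mean,
                "p_raw": p,
                "deeper": a if med_a >= med_b else b,
            }
        )
    pairs = pd.DataFrame(rows)
    pairs["p_adj"] = multipletests(pairs["p_raw"], method="fdr_bh")[1]
    p_used = pairs["p_adj"] if use_adjusted else pairs["p_raw"]
    pairs["flagged"] = (pairs["fold_change"] > fc_min) & (p_used < p_max)

    medians = profile.medians()
    overall = float(np.median(list(medians.values())))
    deviation = np.sqrt(fc_min)  # a truly shifted chromosome moves the pair
    verdicts = {}                # fold change mostly by its own deviation
    for chrom in chroms:
        mine = pairs[(pairs["chrom_a"] == chrom) | (pairs["chrom_b"] == chrom)]
        flagged = mine[mine["flagged"]]
        rel = medians[chrom] / overall if overall > 0 else 1.0
        if len(flagged) == 0 or (deviation >= rel >= 1.0 / deviation):
            # unflagged, or flagged only against another (shifted) chromosome
            # while sitting at the majority depth itself
            verdicts[chrom] = EUPLOID
        elif (flagged["deeper"] == chrom).all() and rel > deviation:
            verdicts[chrom] = (
                GAIN if len(flagged) == len(chroms) - 1 else AMBIGUOUS
            )
        elif (flagged["deeper"] != chrom).all() and rel < 1.0 / deviation:
            verdicts[chrom] = (
                LOSS if len(flagged) == len(chroms) - 1 else AMBIGUOUS
            )
        else:
            verdicts[chrom] = AMBIGUOUS
    return AneuploidyReport(profile.sample_id, pairs, verdicts)


def screen_population(
    profiles: list[DepthProfile],
    fc_min: float = 1.2,
    p_max: float = 1e-20,
    use_adjusted: bool = True,
) -> tuple[float, list[AneuploidyReport]]:
    """Screen every sample; return the aneuploid fraction and the reports."""
    if not profiles:
        raise ValueError("no samples to screen")
    reports = [
        screen_sample(p, fc_min=fc_min, p_max=p_max, use_adjusted=use_adjusted)
        for p in profiles
    ]
    frac = sum(r.is_aneuploid for r in reports) / len(reports)
    return frac, reports
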