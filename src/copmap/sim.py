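"""Synthetic BC1 gamete generator under a two-pathway crossover model.

The generator emulates the BC1 shallow-sequencing experimental design end to end:

* **Class I (interfering) chiasmata** are drawn from a stationary
  gamma-renewal process (shape ``nu`` >= 1) on the cumulative-intensity axis
  of a positional Crossover-Potential map; ``nu = 1`` reduces exactly to a
  Poisson process (no interference), larger ``nu`` gives underdispersed,
  evenly spaced events.
* **Class II (non-interfering) chiasmata** are an independent inhomogeneous
  Poisson draw from the same (or another) intensity.
* **Chiasma-to-chromatid thinning**: every chiasma involves two of the four
  chromatids of a bivalent (one per sister pair, chosen uniformly — no
  chromatid interference) and a gamete inherits a single chromatid, so each
  chiasma is transmitted with probability 1/2 and the mean crossover count
  per gamete is half the mean chiasma count per meiocyte.
* **Shallow sequencing**: per-marker read counts are Poisson at the target
  depth; a marker where the gamete carried the non-tester allele is
  heterozygous in the BC1 plant, so reads split evenly between alleles,
  while tester-allele (homozygous) markers yield the other allele only
  through a symmetric genotyping error ``epsilon``.
* **Aneuploidy**: a configurable fraction of gametes carries a duplicated
  chromosome, which multiplies its sequencing depth by 1.5 (three copies
  instead of two in the BC1 plant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from copmap.aneuploidy import DepthProfile
from copmap.io import HET, HOM_A, CrossoverCall, FocusTable, PopulationCalls, SampleCounts
from copmap.layout import GenomeLayout, MarkerMap
from copmap.tracks import WindowedTrack

CLASS_I = "I"
CLASS_II = "II"

# burn-in, in units of mean inter-event distance, before the renewal process
# is treated as stationary
_RENEWAL_BURN = 25.0


class PositionSampler:
    """Maps uniform(0, 1) draws to bp positions via the inverse cumulative
    intensity of a Crossover-Potential map (or a uniform density)."""

    def __init__(self, length: int, intensity: WindowedTrack | None = None,
                 chrom: str | None = None):
        self.length = int(length)
        if intensity is None:
            self._edges = None
            return
        if chrom is None or chrom not in intensity.starts:
            raise ValueError(f"intensity track lacks chromosome {chrom!r}")
        starts = intensity.starts[chrom]
        values = np.asarray(intensity.values[chrom], dtype=float)
        if np.any(values < 0) or np.any(~np.isfinite(values)):
            raise ValueError("intensity values must be finite and non-negative")
        if values.sum() <= 0:
            raise ValueError(f"intensity on {chrom} has zero total mass")
        # treat each window value as a constant density over the bin between
        # consecutive window midpoints (nearest-neighbour in overlap regions)
        mids = np.minimum(starts + intensity.window_size / 2.0, self.length)
        edges = np.concatenate([[0.0], (mids[:-1] + mids[1:]) / 2.0, [float(self.length)]])
        mass = values * np.diff(edges)
        cum = np.concatenate([[0.0], np.cumsum(mass)])
        self._edges = edges
        self._cum = cum / cum[-1]

    def positions(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self._edges is None:
            return u * self.length
        return np.interp(u, self._cum, self._edges)


def _stationary_renewal(total: float, nu: float, rng: np.random.Generator) -> np.ndarray:
    """Event times in [0, total) of a rate-1 gamma-renewal process (shape nu)
    started in its stationary regime (via burn-in from -_RENEWAL_BURN)."""
    start = -_RENEWAL_BURN
    chunk = max(16, int((total - start) * 1.5) + 8)
    gaps = rng.gamma(nu, 1.0 / nu, size=chunk)
    times = start + np.cumsum(gaps)
    while times[-1] < total:
        more = rng.gamma(nu, 1.0 / nu, size=chunk)
        times = np.concatenate([times, times[-1] + np.cumsum(more)])
    return times[(times >= 0.0) & (times < total)]


def sample_class_I(
    chrom_length: int,
    mean_count: float,
    nu: float,
    rng: np.random.Generator,
    intensity: WindowedTrack | None = None,
    chrom: str | None = None,
    obligate: bool = False,
    _sampler: PositionSampler | None = None,
) -> np.ndarray:
    """Draw interfering class I chiasma positions on one chromosome.

    Events come from a stationary gamma-renewal process with shape ``nu`` on
    the cumulative-intensity axis, rescaled so the expected count equals
    ``mean_count``.  With ``obligate=True`` chromosomes with zero events are
    redrawn (truncated-at->=1 scheme).
    """
    if nu < 1:
        raise ValueError("interference shape nu must be >= 1")
    if mean_count < 0:
        raise ValueError("mean_count must be >= 0")
    if mean_count == 0:
        if obligate:
            raise ValueError("obligate crossover requires mean_count > 0")
        return np.array([], dtype=float)
    sampler = _sampler or PositionSampler(chrom_length, intensity, chrom)
    for _ in range(10_000):
        events = _stationary_renewal(mean_count, nu, rng)
        if len(events) or not obligate:
            return np.sort(sampler.positions(events / mean_count))
    raise RuntimeError("obligate redraw failed to produce an event")


def sample_class_II(
    chrom_length: int,
    mean_count: float,
    rng: np.random.Generator,
    intensity: WindowedTrack | None = None,
    chrom: str | None = None,
    _sampler: PositionSampler | None = None,
) -> np.ndarray:
    """Draw non-interfering class II chiasma positions (inhomogeneous Poisson)."""
    if mean_count < 0:
        raise ValueError("mean_count must be >= 0")
    n = rng.poisson(mean_count)
    if n == 0:
        return np.array([], dtype=float)
    sampler = _sampler or PositionSampler(chrom_length, intensity, chrom)
    return np.sort(sampler.positions(rng.random(n)))


@dataclass
class Meiosis:
    """Chiasma positions (bp) and pathway classes, per chromosome."""

    positions: dict[str, np.ndarray]
    classes: dict[str, np.ndarray]  # array of CLASS_I / CLASS_II strings

    def n_chiasmata(self, cls: str | None = None) -> int:
        if cls is None:
            return sum(len(p) for p in self.positions.values())
        return sum(int(np.sum(c == cls)) for c in self.classes.values())


@dataclass
class GameteGenotype:
    """Transmitted chromatid mosaic: breakpoints and alternating parental
    origin per chromosome, starting from ``left_origin``."""

    breakpoints: dict[str, np.ndarray]
    left_origin: dict[str, str]  # "A" (tester parent) or "B"
    co_classes: dict[str, np.ndarray] = field(default_factory=dict)

    def allele_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Parental origin ('A'/'B') at each position."""
        bps = self.breakpoints.get(chrom, np.array([]))
        origin = self.left_origin.get(chrom, "A")
        n_flips = np.searchsorted(bps, np.asarray(pos), side="right")
        even = n_flips % 2 == 0
        other = "B" if origin == "A" else "A"
        return np.where(even, origin, other)

    @property
    def n_crossovers(self) -> int:
        return sum(len(b) for b in self.breakpoints.values())


@dataclass
class PathwayParams:
    """Per-sex chiasma formation parameters.

    ``class1_mean`` / ``class2_mean`` are mean chiasma counts per chromosome
    per meiosis (a scalar applies to every chromosome; a dict sets them per
    chromosome).  The transmitted-gamete crossover mean is half of these.
    """

    class1_mean: float | dict[str, float] = 2.0
    nu: float = 1.0
    class2_mean: float | dict[str, float] = 0.0
    obligate: bool = False

    def mean_for(self, which: int, chrom: str) -> float:
        src = self.class1_mean if which == 1 else self.class2_mean
        value = src.get(chrom, 0.0) if isinstance(src, dict) else float(src)
        if value < 0:
            raise ValueError("chiasma means must be >= 0")
        return value


@dataclass
class SimConfig:
    """Full parameterization of the synthetic meiosis + sequencing generator."""

    layout: GenomeLayout
    female: PathwayParams = field(default_factory=PathwayParams)
    male: PathwayParams = field(default_factory=PathwayParams)
    intensity: WindowedTrack | None = None
    marker_density_per_mb: float = 25.0
    depth: float = 2.0
    error_rate: float = 0.005
    dropout: float = 0.0
    aneuploidy_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not (0 <= self.dropout <= 1):
            raise ValueError("dropout must be in [0, 1]")
        if not (0 <= self.aneuploidy_rate <= 1):
            raise ValueError("aneuploidy_rate must be in [0, 1]")

    def params(self, sex: str) -> PathwayParams:
        return self.female if sex == "female" else self.male


def nrz_masked_intensity(layout: GenomeLayout, bin_size: int = 100_000) -> WindowedTrack:
    """Uniform intensity with hard zeros inside every NRZ: the minimal
    positional model under which centromeric regions never recombine."""
    starts = {}
    values = {}
    for chrom, length in layout.chromosomes:
        s = np.arange(0, length, bin_size, dtype=np.int64)
        v = np.ones(len(s), dtype=float)
        nrz = layout.nrz.get(chrom)
        if nrz is not None:
            mid = np.minimum(s + bin_size / 2, length)
            v[(mid >= nrz[0]) & (mid < nrz[1])] = 0.0
        starts[chrom] = s
        values[chrom] = v
    return WindowedTrack(bin_size, bin_size, starts, values, "raw_count")


def make_marker_map(layout: GenomeLayout, density_per_mb: float,
                    rng: np.random.Generator) -> MarkerMap:
    """Uniformly placed diagnostic markers at the given genome-wide density."""
    positions = {}
    for chrom, length in layout.chromosomes:
        n = rng.poisson(density_per_mb * length / 1e6)
        pos = np.unique(rng.integers(0, length, size=n))
        positions[chrom] = pos.astype(np.int64)
    return MarkerMap(positions)


def make_meiosis(cfg: SimConfig, sex: str, rng: np.random.Generator,
                 samplers: dict[str, PositionSampler] | None = None) -> Meiosis:
    par = cfg.params(sex)
    positions = {}
    classes = {}
    for chrom, length in cfg.layout.chromosomes:
        sampler = samplers[chrom] if samplers else PositionSampler(length, cfg.intensity, chrom)
        p1 = sample_class_I(length, par.mean_for(1, chrom), par.nu, rng,
                            obligate=par.obligate, _sampler=sampler)
        p2 = sample_class_II(length, par.mean_for(2, chrom), rng, _sampler=sampler)
        pos = np.concatenate([p1, p2])
        cls = np.concatenate([np.repeat(CLASS_I, len(p1)), np.repeat(CLASS_II, len(p2))])
        order = np.argsort(pos, kind="stable")
        positions[chrom] = pos[order]
        classes[chrom] = cls[order]
    return Meiosis(positions, classes)


def thin_to_gamete(meiosis: Meiosis, rng: np.random.Generator) -> GameteGenotype:
    """Assign each chiasma to two non-sister chromatids uniformly, pick one
    of the four chromatids per chromosome as the transmitted one, and return
    its mosaic.  Each chiasma is transmitted with probability exactly 1/2."""
    breakpoints = {}
    origins = {}
    kept_classes = {}
    for chrom, pos in meiosis.positions.items():
        n = len(pos)
        # chromatids 0,1 = sisters of parent A homolog; 2,3 = parent B
        c_a = rng.integers(0, 2, size=n)
        c_b = 2 + rng.integers(0, 2, size=n)
        gamete = int(rng.integers(0, 4))
        hit = (c_a == gamete) | (c_b == gamete)
        breakpoints[chrom] = pos[hit]
        kept_classes[chrom] = meiosis.classes[chrom][hit]
        origins[chrom] = "A" if gamete < 2 else "B"
    return GameteGenotype(breakpoints, origins, kept_classes)


@dataclass
class SimResult:
    """Ground truth of one simulated BC1 population."""

    sex: str
    sample_ids: list[str]
    gametes: list[GameteGenotype]
    truth: pd.DataFrame          # sample_id, chrom, pos, co_class
    chiasmata: pd.DataFrame      # sample_id, n_class1 (foci analogue), n_class2
    aneuploid: pd.DataFrame      # sample_id, chrom (duplicated)

    def truth_population(self, genotype_label: str = "sim") -> PopulationCalls:
        """The truth table as a PopulationCalls (1-bp breakpoint intervals)."""
        calls = [
            CrossoverCall(row.sample_id, row.chrom, int(row.pos), int(row.pos) + 1,
                          HOM_A, HET)
            for row in self.truth.itertuples()
        ]
        return PopulationCalls(genotype_label, self.sex, list(self.sample_ids), calls)

    def focus_table(self, genotype_label: str = "sim") -> FocusTable:
        """Class I chiasma counts per meiocyte — the MLH1/HEI10 foci analogue."""
        return FocusTable(genotype_label, self.sex,
                          self.chiasmata["n_class1"].to_numpy())


def simulate_population(cfg: SimConfig, n_gametes: int, sex: str,
                        rng: np.random.Generator | None = None) -> SimResult:
    """Simulate ``n_gametes`` independent meioses and transmitted gametes."""
    if n_gametes <= 0:
        raise ValueError("n_gametes must be positive")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    samplers = {
        chrom: PositionSampler(length, cfg.intensity, chrom)
        for chrom, length in cfg.layout.chromosomes
    }
    sample_ids = [f"{sex[0]}{i:05d}" for i in range(n_gametes)]
    gametes = []
    truth_rows = []
    chiasma_rows = []
    aneuploid_rows = []
    for sid in sample_ids:
        meiosis = make_meiosis(cfg, sex, rng, samplers)
        gamete = thin_to_gamete(meiosis, rng)
        gametes.append(gamete)
        chiasma_rows.append(
            {
                "sample_id": sid,
                "n_class1": meiosis.n_chiasmata(CLASS_I),
                "n_class2": meiosis.n_chiasmata(CLASS_II),
            }
        )
        for chrom in cfg.layout.names:
            for pos, cls in zip(gamete.breakpoints[chrom], gamete.co_classes[chrom]):
                truth_rows.append(
                    {"sample_id": sid, "chrom": chrom, "pos": int(pos), "co_class": cls}
                )
        if cfg.aneuploidy_rate > 0 and rng.random() < cfg.aneuploidy_rate:
            dup = cfg.layout.names[rng.integers(0, len(cfg.layout.names))]
            aneuploid_rows.append({"sample_id": sid, "chrom": dup})
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "chrom", "pos", "co_class"])
    chiasmata = pd.DataFrame(chiasma_rows, columns=["sample_id", "n_class1", "n_class2"])
    aneuploid = pd.DataFrame(aneuploid_rows, columns=["sample_id", "chrom"])
    return SimResult(sex, sample_ids, gametes, truth, chiasmata, aneuploid)


def sequence_gamete(
    gamete: GameteGenotype,
    markers: MarkerMap,
    depth: float,
    error_rate: float,
    rng: np.random.Generator,
    dropout: float = 0.0,
    duplicated_chrom: str | None = None,
    sample_id: str = "sample",
    sex: str = "unknown",
    genotype_label: str = "",
) -> SampleCounts:
    """Emit shallow-sequencing marker allele counts for one gamete."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    frames = []
    for chrom, pos in markers.positions.items():
        lam = depth * (1.0 - dropout)
        if chrom == duplicated_chrom:
            lam *= 1.5  # three copies instead of two in the BC1 plant
        n = rng.poisson(lam, size=len(pos))
        allele = gamete.allele_at(chrom, pos)
        # BC1: gamete allele B => plant heterozygous, reads split evenly;
        # gamete allele A => homozygous tester, B reads arise only from error
        p_b = np.where(allele == "B", 0.5, error_rate)
        reads_b = rng.binomial(n, p_b)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "reads_A": n - reads_b, "reads_B": reads_b}
            )
        )
    counts = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "reads_A", "reads_B"]
    )
    return SampleCounts(sample_id, counts, sex=sex, genotype_label=genotype_label)


def simulate_counts(
    cfg: SimConfig, n_gametes: int, sex: str,
    rng: np.random.Generator | None = None,
    markers: MarkerMap | None = None,
    genotype_label: str = "sim",
) -> tuple[list[SampleCounts], MarkerMap, SimResult]:
    """Full generator: meioses -> gametes -> per-marker allele counts."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if markers is None:
        markers = make_marker_map(cfg.layout, cfg.marker_density_per_mb, rng)
    result = simulate_population(cfg, n_gametes, sex, rng)
    dup = dict(zip(result.aneuploid["sample_id"], result.aneuploid["chrom"]))
    samples = [
        sequence_gamete(
            gamete,
            markers,
            cfg.depth,
            cfg.error_rate,
            rng,
            dropout=cfg.dropout,
            duplicated_chrom=dup.get(sid),
            sample_id=sid,
            sex=sex,
            genotype_label=genotype_label,
        )
        for sid, gamete in zip(result.sample_ids, result.gametes)
    ]
    return samples, markers, result


def simulate_depth_profile(
    layout: GenomeLayout,
    depth: float,
    rng: np.random.Generator,
    window: int = 100_000,
    duplicated_chrom: str | None = None,
    read_length: int = 150,
    sample_id: str = "sample",
) -> DepthProfile:
    """Per-window sequencing depth of one sample over non-overlapping windows.

    Read counts per window are Poisson at the expected coverage; a duplicated
    chromosome has 1.5x depth.  This mimics a whole-genome depth profile
    (every read counts), as opposed to marker-restricted allele counts.
    """
    depths = {}
    for chrom, length in layout.chromosomes:
        starts = np.arange(0, length, window, dtype=np.int64)
        sizes = np.minimum(starts + window, length) - starts
        lam = depth * sizes / read_length
        if chrom == duplicated_chrom:
            lam = lam * 1.5
        reads = rng.poisson(lam)
        depths[chrom] = reads * read_length / sizes
    return DepthProfile(sample_id, window, depths)
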