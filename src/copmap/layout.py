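"""Genome layout and diagnostic-marker map: the coordinate frame of the pipeline.

Files use 1-based inclusive coordinates (the convention of SNP tables);
internally every interval is 0-based half-open.  The readers/writers in this
module are the only place the offset changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class LayoutError(ValueError):
    """Raised for malformed genome-layout or marker files."""


@dataclass
class GenomeLayout:
    """Chromosome lengths, centromere midpoints and non-recombining zones.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    centromere_mid
        Centromere midpoint per chromosome (bp, 0-based).
    nrz
        Non-Recombining Zone per chromosome as a 0-based half-open
        ``(start, end)`` interval spanning the centromere.  Chromosomes
        without a defined NRZ are simply absent.
    excluded_for_interference
        Chromosomes excluded from interference (and related comparative)
        analyses, e.g. because of structural rearrangements.
    """

    chromosomes: list[tuple[str, int]]
    centromere_mid: dict[str, int] = field(default_factory=dict)
    nrz: dict[str, tuple[int, int]] = field(default_factory=dict)
    excluded_for_interference: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise LayoutError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise LayoutError(f"chromosome {name}: non-positive length {length}")
        lengths = dict(self.chromosomes)
        for name, mid in self.centromere_mid.items():
            if name not in lengths:
                raise LayoutError(f"centromere for unknown chromosome {name}")
            if not (0 <= mid < lengths[name]):
                raise LayoutError(f"centromere midpoint of {name} outside chromosome")
        for name, (s, e) in self.nrz.items():
            if name not in lengths:
                raise LayoutError(f"NRZ for unknown chromosome {name}")
            if not (0 <= s < e <= lengths[name]):
                raise LayoutError(f"NRZ interval of {name} invalid: ({s}, {e})")
        unknown = self.excluded_for_interference - set(lengths)
        if unknown:
            raise LayoutError(f"excluded chromosomes not in layout: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length(self, name: str) -> int:
        for n, length in self.chromosomes:
            if n == name:
                return length
        raise KeyError(name)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


@dataclass
class MarkerMap:
    """Per-chromosome sorted positions of diagnostic SNP markers (0-based)."""

    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(pos) <= 0):
                raise LayoutError(f"marker positions on {name} not strictly increasing")
            self.positions[name] = pos

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def contains(self, chrom: str, pos: int) -> bool:
        p = self.positions.get(chrom)
        if p is None:
            return False
        i = np.searchsorted(p, pos)
        return bool(i < len(p) and p[i] == pos)


# TAIR10 chromosome lengths; centromere midpoints and NRZ bounds are the
# centromere-spanning intervals in which no crossover is observed in any
# genotype (rounded to 100 kb).
_TAIR10 = [
    # name, length, cen_mid, nrz_start, nrz_end
    ("chr1", 30_427_671, 15_086_000, 13_000_000, 17_200_000),
    ("chr2", 19_698_289, 3_607_000, 2_600_000, 5_000_000),
    ("chr3", 23_459_830, 13_587_000, 12_400_000, 15_100_000),
    ("chr4", 18_585_056, 3_956_000, 2_800_000, 5_200_000),
    ("chr5", 26_975_502, 11_725_000, 10_600_000, 13_100_000),
]


def arabidopsis_layout() -> GenomeLayout:
    """The five-chromosome *Arabidopsis thaliana* (Col-0/TAIR10) layout.

    Chromosome 4 is flagged excluded-for-interference: it carries a
    translocation associated with the HEI10 transgene and a megabase-scale
    inversion in the Ler parent, which bias interference and comparative
    landscape analyses.
    """
    return GenomeLayout(
        chromosomes=[(n, l) for n, l, _, _, _ in _TAIR10],
        centromere_mid={n: c for n, _, c, _, _ in _TAIR10},
        nrz={n: (s, e) for n, _, _, s, e in _TAIR10},
        excluded_for_interference={"chr4"},
    )


def read_genome_layout(path) -> GenomeLayout:
    """Read a genome layout TSV.

    Expected columns: ``chrom``, ``length``, optionally ``centromere_mid``,
    ``nrz_start``, ``nrz_end`` (1-based inclusive) and ``excluded_flag``
    (0/1).  Malformed rows raise :class:`LayoutError` naming the line.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "chrom" not in df.columns or "length" not in df.columns:
        raise LayoutError(f"{path}: required columns 'chrom' and 'length' missing")
    chromosomes: list[tuple[str, int]] = []
    cen: dict[str, int] = {}
    nrz: dict[str, tuple[int, int]] = {}
    excluded: set[str] = set()
    seen: set[str] = set()
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        name = str(row["chrom"])
        if name in seen:
            raise LayoutError(f"{path}, line {line}: duplicate chromosome {name}")
        seen.add(name)
        length = int(row["length"])
        if length <= 0:
            raise LayoutError(f"{path}, line {line}: non-positive length")
        chromosomes.append((name, length))
        if "centromere_mid" in df.columns and pd.notna(row["centromere_mid"]):
            mid = int(row["centromere_mid"]) - 1
            if not (0 <= mid < length):
                raise LayoutError(f"{path}, line {line}: centromere outside chromosome")
            cen[name] = mid
        has_nrz = (
            "nrz_start" in df.columns
            and "nrz_end" in df.columns
            and pd.notna(row["nrz_start"])
            and pd.notna(row["nrz_end"])
        )
        if has_nrz:
            s, e = int(row["nrz_start"]) - 1, int(row["nrz_end"])
            if e <= s:
                raise LayoutError(f"{path}, line {line}: nrz_end < nrz_start")
            if not (0 <= s and e <= length):
                raise LayoutError(f"{path}, line {line}: NRZ outside chromosome")
            nrz[name] = (s, e)
        if "excluded_flag" in df.columns and pd.notna(row["excluded_flag"]):
            if int(row["excluded_flag"]):
                excluded.add(name)
    return GenomeLayout(chromosomes, cen, nrz, excluded)


def write_genome_layout(layout: GenomeLayout, path) -> None:
    rows = []
    for name, length in layout.chromosomes:
        nrz = layout.nrz.get(name)
        rows.append(
            {
                "chrom": name,
                "length": length,
                "centromere_mid": layout.centromere_mid.get(name, np.nan),
                "nrz_start": nrz[0] + 1 if nrz else np.nan,
                "nrz_end": nrz[1] if nrz else np.nan,
                "excluded_flag": int(name in layout.excluded_for_interference),
            }
        )
    df = pd.DataFrame(rows)
    if layout.centromere_mid:
        df["centromere_mid"] = df["centromere_mid"] + 1
    df.to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> MarkerMap:
    """Read a marker TSV with columns ``chrom``, ``pos`` (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    positions = {
        str(chrom): np.sort(sub["pos"].to_numpy(dtype=np.int64)) - 1
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    return MarkerMap(positions)


def write_marker_map(markers: MarkerMap, path) -> None:
    frames = [
        pd.DataFrame({"chrom": chrom, "pos": pos + 1})
        for chrom, pos in markers.positions.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
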