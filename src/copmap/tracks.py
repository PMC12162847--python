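"""Sliding-window tracks: the shared container for CO landscapes, CO_P maps
and genomic feature tracks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW_COUNT = "raw_count"
PER_GAMETE = "per_gamete"
PER_CHROM_RELATIVE = "per_chromosome_relative"
PER_GENOME_RELATIVE = "per_genome_relative"

_NORMALIZATIONS = {RAW_COUNT, PER_GAMETE, PER_CHROM_RELATIVE, PER_GENOME_RELATIVE}


def window_starts(length: int, window: int, step: int) -> np.ndarray:
    """0-based start positions of sliding windows tiling ``[0, length)``.

    The final windows may be truncated at the chromosome end; a window is
    emitted for every start < length.
    """
    if step <= 0 or window <= 0:
        raise ValueError("window and step must be positive")
    if step > window:
        raise ValueError("step must not exceed window size")
    return np.arange(0, length, step, dtype=np.int64)


@dataclass
class WindowedTrack:
    """One value per sliding window, for every chromosome.

    ``starts`` and ``values`` are parallel per-chromosome arrays; window
    ``i`` spans ``[starts[i], starts[i] + window_size)`` clipped to the
    chromosome end.  ``normalization`` records the scale of the values.
    """

    window_size: int
    step: int
    starts: dict[str, np.ndarray]
    values: dict[str, np.ndarray]
    normalization: str = RAW_COUNT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step > self.window_size:
            raise ValueError("step must not exceed window size")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if set(self.starts) != set(self.values):
            raise ValueError("starts and values cover different chromosomes")
        for chrom in self.starts:
            s = np.asarray(self.starts[chrom], dtype=np.int64)
            v = np.asarray(self.values[chrom], dtype=float)
            if len(s) != len(v):
                raise ValueError(f"{chrom}: starts/values length mismatch")
            if len(s) > 1 and np.any(np.diff(s) <= 0):
                raise ValueError(f"{chrom}: window starts not increasing")
            self.starts[chrom] = s
            self.values[chrom] = v

    @property
    def chromosomes(self) -> list[str]:
        return list(self.starts)

    def flat_values(self) -> np.ndarray:
        """All window values concatenated in chromosome order."""
        return np.concatenate([self.values[c] for c in self.starts]) if self.starts else np.array([])

    def same_windowing(self, other: "WindowedTrack") -> bool:
        if (self.window_size, self.step) != (other.window_size, other.step):
            return False
        if set(self.starts) != set(other.starts):
            return False
        return all(np.array_equal(self.starts[c], other.starts[c]) for c in self.starts)

    def copy_with(self, values: dict[str, np.ndarray], normalization: str) -> "WindowedTrack":
        return WindowedTrack(
            self.window_size,
            self.step,
            {c: s.copy() for c, s in self.starts.items()},
            values,
            normalization,
            dict(self.meta),
        )

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for chrom in self.starts:
            s = self.starts[chrom]
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": s + 1,  # 1-based inclusive on disk
                        "end": s + self.window_size,
                        "value": self.values[chrom],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chrom", "start", "end", "value"]
        )

    def write(self, path) -> None:
        """Write a bedGraph-like TSV (1-based inclusive coordinates)."""
        with open(path, "w") as fh:
            fh.write(f"#window_size={self.window_size}\t")
            fh.write(f"step={self.step}\tnormalization={self.normalization}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "WindowedTrack":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing track metadata header")
            meta = dict(
                item.split("=", 1) for item in header.lstrip("#").strip().split("\t")
            )
            df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
        starts = {}
        values = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            starts[str(chrom)] = sub["start"].to_numpy(dtype=np.int64) - 1
            values[str(chrom)] = sub["value"].to_numpy(dtype=float)
        return cls(
            int(meta["window_size"]),
            int(meta["step"]),
            starts,
            values,
            meta.get("normalization", RAW_COUNT),
        )
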