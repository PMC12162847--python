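"""Sample-level domain types and their TSV readers/writers.

BC1 genotype vocabulary: each BC1 individual reports one gamete of the hybrid
parent against the recurrent (tester) parent background.  A region where the
gamete carried the tester allele is scored HOM_A; a region where it carried
the other parent's allele is scored HET.  File coordinates are 1-based
inclusive; in-memory coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from copmap.layout import MarkerMap

HOM_A = "HOM_A"
HET = "HET"

FEMALE = "female"
MALE = "male"
UNKNOWN = "unknown"


@dataclass
class SampleCounts:
    """Per-marker parental allele read counts for one BC1 individual.

    ``counts`` has columns ``chrom``, ``pos`` (0-based), ``reads_A``
    (reads supporting the recurrent/tester parent allele) and ``reads_B``.
    """

    sample_id: str
    counts: pd.DataFrame
    sex: str = UNKNOWN
    genotype_label: str = ""

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE, UNKNOWN):
            raise ValueError(f"bad sex label {self.sex!r}")
        required = {"chrom", "pos", "reads_A", "reads_B"}
        if not required.issubset(self.counts.columns):
            raise ValueError(f"counts missing columns {required - set(self.counts.columns)}")
        if (self.counts[["reads_A", "reads_B"]] < 0).to_numpy().any():
            raise ValueError(f"sample {self.sample_id}: negative read counts")

    @property
    def total_reads(self) -> int:
        return int(self.counts["reads_A"].sum() + self.counts["reads_B"].sum())

    def per_chromosome(self, chrom: str) -> pd.DataFrame:
        sub = self.counts[self.counts["chrom"] == chrom]
        return sub.sort_values("pos")


@dataclass
class CrossoverCall:
    """One inferred crossover: the breakpoint lies in [left_bound, right_bound]."""

    sample_id: str
    chromosome: str
    left_bound: int
    right_bound: int
    left_state: str
    right_state: str
    n_support_left: int = 0
    n_support_right: int = 0

    def __post_init__(self) -> None:
        if self.left_bound >= self.right_bound:
            raise ValueError(
                f"{self.sample_id} {self.chromosome}: empty breakpoint interval "
                f"[{self.left_bound}, {self.right_bound}]"
            )
        if self.left_state == self.right_state:
            raise ValueError("states must differ across a crossover breakpoint")

    @property
    def midpoint(self) -> float:
        return (self.left_bound + self.right_bound) / 2.0


@dataclass
class FocusTable:
    """Cytological MLH1/HEI10 co-focus counts, one integer per meiocyte."""

    genotype_label: str
    sex: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if len(c) and (np.any(c < 0) or np.any(c != np.floor(c))):
            raise ValueError("focus counts must be non-negative integers")
        self.counts = c.astype(np.int64)

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))


@dataclass
class PopulationCalls:
    """All crossover calls of one BC1 population.

    ``sample_ids`` lists every retained gamete, including those without any
    call, so per-gamete rates and presence/absence statistics use the right
    denominator.
    """

    genotype_label: str
    sex: str
    sample_ids: list[str]
    calls: list[CrossoverCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ValueError("population must contain at least one gamete")
        known = set(self.sample_ids)
        for call in self.calls:
            if call.sample_id not in known:
                raise ValueError(f"call for unknown sample {call.sample_id}")

    @property
    def n_gametes(self) -> int:
        return len(self.sample_ids)

    def counts_per_gamete(self) -> np.ndarray:
        """Number of calls per gamete, in sample_ids order (zeros included)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        out = np.zeros(len(self.sample_ids), dtype=np.int64)
        for call in self.calls:
            out[index[call.sample_id]] += 1
        return out

    def midpoints(self, chrom: str) -> np.ndarray:
        return np.sort(
            np.array([c.midpoint for c in self.calls if c.chromosome == chrom])
        )


def read_sample_counts(path, markers: MarkerMap | None = None) -> SampleCounts:
    """Read a per-sample marker count TSV.

    Metadata lines ``#sample_id=...``, ``#sex=...``, ``#genotype=...`` precede
    a header with columns ``sample_id``, ``chrom``, ``pos`` (1-based),
    ``reads_A``, ``reads_B``.  If ``markers`` is given, rows at positions
    absent from the map are rejected.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        offset = 0
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("#").strip().partition("=")
            meta[key] = value
            offset += 1
        fh.seek(0)
        for _ in range(offset):
            fh.readline()
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    if (df[["reads_A", "reads_B"]] < 0).to_numpy().any():
        raise ValueError(f"{path}: negative read counts")
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64) - 1
    if markers is not None:
        for chrom, sub in df.groupby("chrom"):
            known = markers.positions.get(str(chrom))
            if known is None:
                raise ValueError(f"{path}: chromosome {chrom} not in marker map")
            idx = np.searchsorted(known, sub["pos"].to_numpy())
            idx = np.clip(idx, 0, len(known) - 1)
            bad = known[idx] != sub["pos"].to_numpy()
            if bad.any():
                pos = sub["pos"].to_numpy()[bad][0] + 1
                raise ValueError(f"{path}: marker {chrom}:{pos} not in marker map")
    sample_id = meta.get("sample_id") or (
        str(df["sample_id"].iloc[0]) if "sample_id" in df.columns and len(df) else "sample"
    )
    return SampleCounts(
        sample_id=sample_id,
        counts=df[["chrom", "pos", "reads_A", "reads_B"]].reset_index(drop=True),
        sex=meta.get("sex", UNKNOWN),
        genotype_label=meta.get("genotype", ""),
    )


def write_sample_counts(sample: SampleCounts, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sample_id={sample.sample_id}\n")
        fh.write(f"#sex={sample.sex}\n")
        fh.write(f"#genotype={sample.genotype_label}\n")
        out = sample.counts.copy()
        out.insert(0, "sample_id", sample.sample_id)
        out["pos"] = out["pos"] + 1
        out.to_csv(fh, sep="\t", index=False)


_CALL_COLUMNS = [
    "sample_id",
    "chrom",
    "left_bound",
    "right_bound",
    "midpoint",
    "left_state",
    "right_state",
    "n_support_left",
    "n_support_right",
]


def write_crossover_table(calls: list[CrossoverCall], path) -> None:
    """Write calls as TSV, one crossover per row.

    Rows are sorted by (sample, chromosome, left bound) so output is
    deterministic regardless of call order.
    """
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.chromosome,
            "left_bound": c.left_bound + 1,
            "right_bound": c.right_bound,
            "midpoint": (c.left_bound + 1 + c.right_bound) / 2.0,
            "left_state": c.left_state,
            "right_state": c.right_state,
            "n_support_left": c.n_support_left,
            "n_support_right": c.n_support_right,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=_CALL_COLUMNS)
    if len(df):
        df = df.sort_values(["sample_id", "chrom", "left_bound"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_crossover_table(path) -> list[CrossoverCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    return [
        CrossoverCall(
            sample_id=row.sample_id,
            chromosome=row.chrom,
            left_bound=int(row.left_bound) - 1,
            right_bound=int(row.right_bound),
            left_state=row.left_state,
            right_state=row.right_state,
            n_support_left=int(row.n_support_left),
            n_support_right=int(row.n_support_right),
        )
        for row in df.itertuples()
    ]


def read_focus_table(path) -> list[FocusTable]:
    """Read a focus-count TSV with columns ``genotype``, ``sex``, ``count``."""
    df = pd.read_csv(path, sep="\t")
    return [
        FocusTable(str(genotype), str(sex), sub["count"].to_numpy())
        for (genotype, sex), sub in df.groupby(["genotype", "sex"], sort=False)
    ]
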