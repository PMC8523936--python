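"""Bin tables, sparse contact maps and interval I/O.

The on-disk dialect is the HiC-Pro pair of files: a ``.bed`` file listing
the genomic bins (chrom, start, end, bin id) and a ``.matrix`` file of
whitespace-separated ``bin_i bin_j value`` triplets.  Bin ids on disk are
1-based and genome-wide consecutive; in memory bins are indexed 0..n-1.
Coordinates are 0-based half-open everywhere.  Gzipped files are handled
transparently (pandas dispatches on the ``.gz`` suffix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinTable",
    "ContactMap",
    "SampleSet",
    "FormatError",
    "read_contact_map",
    "write_contact_map",
    "merge_maps",
    "max_resolution",
    "read_track",
    "write_track",
]


class FormatError(ValueError):
    """Malformed input file or inconsistent bin/record structure."""


# ---------------------------------------------------------------------------
# BinTable
# ---------------------------------------------------------------------------


@dataclass
class BinTable:
    """Genome-wide ordered table of uniform bins.

    Bins are sorted by (chrom, start), non-overlapping, of uniform width
    per resolution except possibly the last bin of each chromosome.
    """

    chroms: np.ndarray  # str array, one per bin
    starts: np.ndarray  # int, 0-based
    ends: np.ndarray  # int, half-open
    resolution: int = field(default=0)

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise FormatError("bin table column lengths differ")
        if np.any(self.ends <= self.starts):
            raise FormatError("bin with end <= start")
        widths = self.ends - self.starts
        if self.resolution == 0:
            self.resolution = int(widths.max()) if len(widths) else 0
        # per-chromosome checks: sorted, non-overlapping, uniform width
        # except the terminal bin
        for chrom in self.chrom_names:
            sel = self.chroms == chrom
            s, e = self.starts[sel], self.ends[sel]
            if np.any(np.diff(s) <= 0):
                raise FormatError(f"bins not sorted on {chrom}")
            if np.any(s[1:] < e[:-1]):
                raise FormatError(f"overlapping bins on {chrom}")
            w = e - s
            if len(w) > 1 and np.any(w[:-1] != self.resolution):
                raise FormatError(f"non-uniform bin width on {chrom}")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def chrom_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chroms:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: int(self.ends[self.chroms == c].max()) for c in self.chrom_names}

    def bin_range(self, chrom: str) -> tuple[int, int]:
        """Half-open [first, last) bin-index range of one chromosome."""
        idx = np.flatnonzero(self.chroms == chrom)
        if len(idx) == 0:
            raise KeyError(chrom)
        return int(idx[0]), int(idx[-1]) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "bin_id": np.arange(len(self), dtype=np.int64),
            }
        )

    @classmethod
    def from_chrom_sizes(cls, sizes: dict[str, int], resolution: int) -> "BinTable":
        chroms, starts, ends = [], [], []
        for chrom, size in sizes.items():
            edges = np.arange(0, size, resolution, dtype=np.int64)
            chroms.extend([chrom] * len(edges))
            starts.extend(edges)
            ends.extend(np.minimum(edges + resolution, size))
        return cls(np.array(chroms, dtype=object), np.array(starts), np.array(ends), resolution)

    @classmethod
    def read_bed(cls, path) -> "BinTable":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "bin_id"],
                         dtype={"chrom": str})
        ids = df["bin_id"].to_numpy()
        if np.any(np.diff(ids) != 1):
            raise FormatError("bin ids not consecutive")
        return cls(df["chrom"].to_numpy(dtype=object),
                   df["start"].to_numpy(), df["end"].to_numpy())

    def write_bed(self, path) -> None:
        df = self.to_frame()
        df["bin_id"] = df["bin_id"] + 1  # 1-based on disk
        df.to_csv(path, sep="\t", header=False, index=False)

    def equals(self, other: "BinTable") -> bool:
        return (
            len(self) == len(other)
            and np.array_equal(self.chroms, other.chroms)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )


# ---------------------------------------------------------------------------
# ContactMap
# ---------------------------------------------------------------------------


@dataclass
class ContactMap:
    """Sparse symmetric binned interaction map in upper-triangle storage."""

    bins: BinTable
    bin1: np.ndarray
    bin2: np.ndarray
    count: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.bin1 = np.asarray(self.bin1, dtype=np.int64)
        self.bin2 = np.asarray(self.bin2, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=float)

    @property
    def resolution(self) -> int:
        return self.bins.resolution

    def __len__(self) -> int:
        return len(self.count)

    @classmethod
    def from_records(
        cls,
        bins: BinTable,
        bin1: np.ndarray,
        bin2: np.ndarray,
        count: np.ndarray,
        normalized: bool = False,
        warn_duplicates: bool = True,
    ) -> "ContactMap":
        """Fold records to the upper triangle and sum duplicate keys."""
        bin1 = np.asarray(bin1, dtype=np.int64)
        bin2 = np.asarray(bin2, dtype=np.int64)
        count = np.asarray(count, dtype=float)
        n = len(bins)
        if len(bin1) and (bin1.min() < 0 or bin2.min() < 0
                          or bin1.max() >= n or bin2.max() >= n):
            raise FormatError("record references unknown bin id")
        if np.any(count < 0):
            raise FormatError("negative interaction value")
        lo = np.minimum(bin1, bin2)
        hi = np.maximum(bin1, bin2)
        key = lo * n + hi
        order = np.argsort(key, kind="stable")
        key, lo, hi, count = key[order], lo[order], hi[order], count[order]
        uniq, first = np.unique(key, return_index=True)
        if len(uniq) != len(key):
            if warn_duplicates:
                warnings.warn("duplicate (i, j) keys summed", stacklevel=2)
            count = np.add.reduceat(count, first)
            lo, hi = lo[first], hi[first]
        return cls(bins, lo, hi, count, normalized=normalized)

    # -- views ------------------------------------------------------------

    def is_cis(self) -> np.ndarray:
        return self.bins.chroms[self.bin1] == self.bins.chroms[self.bin2]

    def cis(self, chrom: str | None = None) -> "ContactMap":
        """Cis records; if ``chrom`` is given, only that chromosome."""
        mask = self.is_cis()
        if chrom is not None:
            mask &= self.bins.chroms[self.bin1] == chrom
        return ContactMap(self.bins, self.bin1[mask], self.bin2[mask],
                          self.count[mask], self.normalized)

    def to_dense(self, chrom: str | None = None) -> np.ndarray:
        """Dense symmetric array; restricted to one chromosome if given."""
        if chrom is None:
            lo, hi = 0, len(self.bins)
            b1, b2, v = self.bin1, self.bin2, self.count
        else:
            lo, hi = self.bins.bin_range(chrom)
            mask = ((self.bin1 >= lo) & (self.bin1 < hi)
                    & (self.bin2 >= lo) & (self.bin2 < hi))
            b1, b2, v = self.bin1[mask], self.bin2[mask], self.count[mask]
        n = hi - lo
        mat = np.zeros((n, n))
        mat[b1 - lo, b2 - lo] = v
        mat[b2 - lo, b1 - lo] = v
        return mat

    def marginals(self, include_trans: bool = True) -> np.ndarray:
        """Per-bin cumulated interaction count (diagonal counted once)."""
        mask = np.ones(len(self), dtype=bool) if include_trans else self.is_cis()
        marg = np.zeros(len(self.bins))
        np.add.at(marg, self.bin1[mask], self.count[mask])
        off = mask & (self.bin1 != self.bin2)
        np.add.at(marg, self.bin2[off], self.count[off])
        return marg

    def total(self) -> float:
        return float(self.count.sum())

    def coarsen(self, resolution: int) -> "ContactMap":
        """Re-bin to a coarser resolution (a multiple of the current one)."""
        if resolution % self.resolution:
            raise ValueError("target resolution must be a multiple of the current one")
        coarse = BinTable.from_chrom_sizes(self.bins.chrom_sizes, resolution)
        # map each fine bin to its coarse bin
        lut = np.empty(len(self.bins), dtype=np.int64)
        for chrom in self.bins.chrom_names:
            flo, fhi = self.bins.bin_range(chrom)
            clo, _ = coarse.bin_range(chrom)
            lut[flo:fhi] = clo + self.bins.starts[flo:fhi] // resolution
        return ContactMap.from_records(coarse, lut[self.bin1], lut[self.bin2],
                                       self.count, self.normalized,
                                       warn_duplicates=False)


@dataclass
class SampleSet:
    """Replicated contact maps for a two-group design."""

    sample_ids: list[str]
    groups: list[str]  # e.g. d90/d110, one per sample
    maps: list[ContactMap]

    def __post_init__(self) -> None:
        if not (len(self.sample_ids) == len(self.groups) == len(self.maps)):
            raise ValueError("sample metadata lengths differ")
        if len(set(self.groups)) != 2:
            raise ValueError("exactly two group levels required")
        ref = self.maps[0].bins
        for m in self.maps[1:]:
            if not m.bins.equals(ref):
                raise ValueError("all maps must share one bin table")

    @property
    def bins(self) -> BinTable:
        return self.maps[0].bins

    @property
    def group_levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def by_group(self, group: str) -> list[ContactMap]:
        return [m for g, m in zip(self.groups, self.maps) if g == group]


# ---------------------------------------------------------------------------
# Contact-map file I/O
# ---------------------------------------------------------------------------


def read_contact_map(matrix_path, bed_path) -> ContactMap:
    """Read a HiC-Pro triplet ``.matrix`` + ``.bed`` pair.

    Lower-triangle entries are folded onto the upper triangle; duplicate
    keys (including an (i,j)/(j,i) pair) are summed with a warning.
    """
    bins = BinTable.read_bed(bed_path)
    tri = pd.read_csv(matrix_path, sep=r"\s+", header=None, comment="#",
                      names=["bin1", "bin2", "count"])
    if len(tri) and tri["count"].min() < 0:
        raise FormatError("negative interaction value")
    b1 = tri["bin1"].to_numpy(dtype=np.int64) - 1
    b2 = tri["bin2"].to_numpy(dtype=np.int64) - 1
    if len(b1) and (b1.min() < 0 or b2.min() < 0
                    or max(b1.max(), b2.max()) >= len(bins)):
        raise FormatError("matrix references bin id outside the bed file")
    return ContactMap.from_records(bins, b1, b2, tri["count"].to_numpy())


def write_contact_map(cmap: ContactMap, matrix_path, bed_path=None) -> None:
    """Write the HiC-Pro dialect (1-based bin ids, upper triangle)."""
    df = pd.DataFrame({"bin1": cmap.bin1 + 1, "bin2": cmap.bin2 + 1,
                       "count": cmap.count})
    if not cmap.normalized:
        df["count"] = df["count"].astype(np.int64)
    df.to_csv(matrix_path, sep="\t", header=False, index=False)
    if bed_path is not None:
        cmap.bins.write_bed(bed_path)


def merge_maps(maps: list[ContactMap]) -> ContactMap:
    """Element-wise sum of raw maps sharing one bin table."""
    if not maps:
        raise ValueError("no maps to merge")
    ref = maps[0].bins
    for m in maps:
        if not m.bins.equals(ref):
            raise ValueError("mismatched bin tables")
        if m.normalized:
            raise ValueError("merge requires raw maps")
    b1 = np.concatenate([m.bin1 for m in maps])
    b2 = np.concatenate([m.bin2 for m in maps])
    v = np.concatenate([m.count for m in maps])
    return ContactMap.from_records(ref, b1, b2, v, warn_duplicates=False)


def max_resolution(
    map_at_finest: ContactMap,
    candidate_resolutions: list[int],
    min_count: float = 1000,
    min_fraction: float = 0.8,
    include_trans: bool = True,
) -> int | None:
    """Finest claimable resolution.

    A resolution can be claimed when at least ``min_fraction`` of its bins
    cumulate at least ``min_count`` interactions (marginal sum, diagonal
    once).  Returns the smallest passing candidate, or None.
    """
    if not candidate_resolutions:
        raise ValueError("empty candidate list")
    for r in candidate_resolutions:
        if r % map_at_finest.resolution:
            raise ValueError("candidates must be multiples of the finest resolution")
    for r in sorted(candidate_resolutions):
        cm = map_at_finest if r == map_at_finest.resolution else map_at_finest.coarsen(r)
        marg = cm.marginals(include_trans=include_trans)
        if np.mean(marg >= min_count) >= min_fraction:
            return r
    return None


# ---------------------------------------------------------------------------
# Interval tracks
# ---------------------------------------------------------------------------


def write_track(intervals: pd.DataFrame, path, fmt: str = "BED") -> None:
    """Write intervals (chrom/start/end + attribute columns) as BED or TSV.

    BED is 0-based half-open, tab-separated, headerless; TSV keeps the
    header and every column.
    """
    required = ["chrom", "start", "end"]
    for col in required:
        if col not in intervals.columns:
            raise ValueError(f"missing column {col!r}")
    if len(intervals) and (intervals["end"] <= intervals["start"]).any():
        raise ValueError("interval with end <= start")
    fmt = fmt.upper()
    if fmt == "BED":
        cols = required + [c for c in intervals.columns if c not in required]
        intervals[cols].to_csv(path, sep="\t", header=False, index=False)
    elif fmt == "TSV":
        intervals.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_track(path, fmt: str = "BED", names: list[str] | None = None) -> pd.DataFrame:
    fmt = fmt.upper()
    if fmt == "BED":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str})
        base = ["chrom", "start", "end"]
        extra = names if names is not None else [f"col{i}" for i in range(3, df.shape[1])]
        df.columns = (base + list(extra))[: df.shape[1]]
    elif fmt == "TSV":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return df
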