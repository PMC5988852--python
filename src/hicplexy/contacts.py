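"""Contact-pair I/O, filtering, and binning into symmetric contact matrices.

Pairs are held in a pandas DataFrame with one row per ligation product:
columns ``read_id, chrom1, pos1, strand1, chrom2, pos2, strand2`` and
optional ``mapq1, mapq2``. Rows are kept in canonical order — chrom1 <=
chrom2 in the genome's chromosome ordering, and pos1 <= pos2 for
same-chromosome pairs — so that duplicate detection and matrix binning
are orientation-independent.

The on-disk format is the same columns as a tab-separated file (header
lines starting with '#' are ignored). This maps 1:1 onto the community
"pairs" standard (readID chr1 pos1 chr2 pos2 strand1 strand2) up to
column order; a converter would only permute columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import FragmentMap, GenomeError, GenomeIndex, GenomicInterval

PAIR_COLUMNS = ["read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
MAPQ_COLUMNS = ["mapq1", "mapq2"]


class PairsError(ValueError):
    """Malformed pairs input."""


@dataclass
class FilterReport:
    """Counts of pairs removed by each filter."""

    n_input: int = 0
    n_duplicate: int = 0
    n_low_mapq: int = 0
    n_far_from_cut: int = 0
    n_retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


class BinScheme:
    """Fixed-width genomic bins with a global (genome-wide) bin index."""

    def __init__(self, genome: GenomeIndex, bin_size: int):
        if bin_size <= 0:
            raise PairsError("bin size must be positive")
        self.genome = genome
        self.bin_size = int(bin_size)
        self._n_bins = {
            c: -(-genome.length(c) // bin_size) for c in genome
        }
        offsets = np.cumsum([0] + [self._n_bins[c] for c in genome])
        self._offset = {c: int(offsets[i]) for i, c in enumerate(genome)}
        self.n_bins_total = int(offsets[-1])
        # reverse lookup arrays
        self._chrom_of_bin = np.empty(self.n_bins_total, dtype=object)
        self._local_of_bin = np.empty(self.n_bins_total, dtype=np.int64)
        self.bin_chrom_rank = np.empty(self.n_bins_total, dtype=np.int64)
        for c in genome:
            off, n = self._offset[c], self._n_bins[c]
            self._chrom_of_bin[off : off + n] = c
            self._local_of_bin[off : off + n] = np.arange(n)
            self.bin_chrom_rank[off : off + n] = genome.rank(c)

    def n_bins(self, chrom: str) -> int:
        return self._n_bins[chrom]

    def offset(self, chrom: str) -> int:
        return self._offset[chrom]

    def bin_of(self, chrom: str, pos) -> np.ndarray | int:
        """Global bin index of position(s) on a chromosome."""
        pos_arr = np.asarray(pos)
        if np.any(pos_arr < 0) or np.any(pos_arr >= self.genome.length(chrom)):
            raise PairsError(f"position outside {chrom}")
        out = self._offset[chrom] + pos_arr // self.bin_size
        return int(out) if np.isscalar(pos) else out

    def bin_interval(self, gbin: int) -> GenomicInterval:
        chrom = str(self._chrom_of_bin[gbin])
        local = int(self._local_of_bin[gbin])
        start = local * self.bin_size
        end = min(start + self.bin_size, self.genome.length(chrom))
        return GenomicInterval(chrom, start, end)

    def chrom_of(self, gbins) -> np.ndarray:
        return self._chrom_of_bin[gbins]

    def bin_ranges(self) -> dict[str, tuple[int, int]]:
        """Global [start, stop) bin range per chromosome."""
        return {
            c: (self._offset[c], self._offset[c] + self._n_bins[c])
            for c in self.genome
        }


class ContactMatrix:
    """Symmetric binned contact counts, stored as an upper-triangular sparse
    matrix over global bins (count(i, j) kept once with i <= j)."""

    def __init__(self, scheme: BinScheme, upper: sp.csr_matrix):
        self.scheme = scheme
        self.upper = upper.tocsr()
        self.upper.sum_duplicates()

    @property
    def total(self) -> float:
        return float(self.upper.sum())

    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric matrix (diagonal not double-counted)."""
        diag = sp.diags(self.upper.diagonal())
        return (self.upper + self.upper.T - diag).tocsr()

    def count(self, i: int, j: int) -> float:
        a, b = min(i, j), max(i, j)
        return self.upper[a, b]

    def dense_block(self, rows: slice, cols: slice) -> np.ndarray:
        return np.asarray(self.symmetric()[rows, cols].todense())

    def to_triples(self, path: str | Path) -> None:
        coo = self.upper.tocoo()
        with open(path, "w") as fh:
            fh.write("#bin_i\tbin_j\tcount\n")
            order = np.lexsort((coo.col, coo.row))
            for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
                fh.write(f"{i}\t{j}\t{v:g}\n")

    def bins_to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in range(self.scheme.n_bins_total):
                iv = self.scheme.bin_interval(g)
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g}\n")


def matrix_from_dense(scheme: BinScheme, dense: np.ndarray) -> ContactMatrix:
    """Build a ContactMatrix from a dense symmetric array (testing aid)."""
    dense = np.asarray(dense, dtype=float)
    if dense.shape != (scheme.n_bins_total, scheme.n_bins_total):
        raise PairsError("dense shape does not match bin scheme")
    if not np.allclose(dense, dense.T):
        raise PairsError("matrix must be symmetric")
    return ContactMatrix(scheme, sp.csr_matrix(np.triu(dense)))


def _canonicalize(df: pd.DataFrame, genome: GenomeIndex) -> pd.DataFrame:
    rank = {c: genome.rank(c) for c in genome}
    r1 = df["chrom1"].map(rank)
    r2 = df["chrom2"].map(rank)
    flip = (r2 < r1) | ((r1 == r2) & (df["pos2"] < df["pos1"]))
    if flip.any():
        df = df.copy()
        for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2"),
                     ("mapq1", "mapq2")):
            if a in df.columns:
                tmp = df.loc[flip, a].copy()
                df.loc[flip, a] = df.loc[flip, b]
                df.loc[flip, b] = tmp
    return df


def make_pairs(
    genome: GenomeIndex,
    chrom1: Sequence[str],
    pos1: Sequence[int],
    strand1: Sequence[str],
    chrom2: Sequence[str],
    pos2: Sequence[int],
    strand2: Sequence[str],
    read_id: Sequence[str] | None = None,
    mapq1: Sequence[int] | None = None,
    mapq2: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Assemble and canonicalise a pairs DataFrame from column arrays."""
    n = len(pos1)
    data = {
        "read_id": list(read_id) if read_id is not None else [f"r{i}" for i in range(n)],
        "chrom1": list(chrom1),
        "pos1": np.asarray(pos1, dtype=np.int64),
        "strand1": list(strand1),
        "chrom2": list(chrom2),
        "pos2": np.asarray(pos2, dtype=np.int64),
        "strand2": list(strand2),
    }
    if mapq1 is not None:
        data["mapq1"] = np.asarray(mapq1, dtype=np.int64)
        data["mapq2"] = np.asarray(mapq2, dtype=np.int64)
    df = pd.DataFrame(data)
    _validate_positions(df, genome)
    return _canonicalize(df, genome).reset_index(drop=True)


def _validate_positions(df: pd.DataFrame, genome: GenomeIndex) -> None:
    for side in ("1", "2"):
        for chrom, sub in df.groupby(f"chrom{side}", sort=False):
            if chrom not in genome:
                first = int(sub.index[0]) + 2  # +2: header + 1-based
                raise PairsError(
                    f"line {first}: unknown chromosome {chrom!r}"
                )
            pos = sub[f"pos{side}"].to_numpy()
            bad = (pos < 0) | (pos >= genome.length(str(chrom)))
            if bad.any():
                first = int(sub.index[bad.argmax()]) + 2
                raise PairsError(f"line {first}: position outside {chrom}")


def read_pairs(path: str | Path, genome: GenomeIndex) -> pd.DataFrame:
    """Read a pairs TSV into a canonicalised DataFrame.

    Lines starting with '#' are headers/comments. Each data line has 7
    required fields and 2 optional mapq fields; anything else is an error
    reported with its line number.
    """
    rows = []
    n_cols = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) not in (7, 9):
                raise PairsError(
                    f"{path}:{ln}: expected 7 or 9 fields, got {len(parts)}"
                )
            if n_cols is None:
                n_cols = len(parts)
            elif len(parts) != n_cols:
                raise PairsError(f"{path}:{ln}: inconsistent field count")
            try:
                row = [
                    parts[0], parts[1], int(parts[2]), parts[3],
                    parts[4], int(parts[5]), parts[6],
                ]
                if n_cols == 9:
                    row += [int(parts[7]), int(parts[8])]
            except ValueError:
                raise PairsError(f"{path}:{ln}: non-integer field") from None
            rows.append(row)
    cols = PAIR_COLUMNS + (MAPQ_COLUMNS if n_cols == 9 else [])
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        df["pos1"] = df["pos1"].astype(np.int64)
        df["pos2"] = df["pos2"].astype(np.int64)
        _validate_positions(df, genome)
        df = _canonicalize(df, genome)
    return df.reset_index(drop=True)


def write_pairs(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in PAIR_COLUMNS + MAPQ_COLUMNS if c in df.columns]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, columns=cols)


def _distance_to_cut(pos: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Distance from each position to the nearest fragment boundary."""
    idx = np.searchsorted(boundaries, pos)
    idx = np.clip(idx, 1, len(boundaries) - 1)
    left = pos - boundaries[idx - 1]
    right = boundaries[idx] - pos
    return np.minimum(left, right)


def filter_pairs(
    df: pd.DataFrame,
    min_mapq: int | None = None,
    dedup: bool = True,
    fragments: FragmentMap | None = None,
    max_frag_distance: int | None = 1000,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove PCR duplicates, low-quality and off-fragment pairs.

    A duplicate is a pair with identical canonical coordinates and strands
    (both mates). The distance-to-cut-site filter is a post-alignment proxy
    for reads not anchored at a restriction site: a valid Hi-C read starts
    near a cut site of the enzyme, so reads farther than
    ``max_frag_distance`` from every cut site are discarded. Filters are
    applied in the order duplicate -> mapq -> cut-site distance and each
    removal is attributed to the first filter that caught it.
    """
    report = FilterReport(n_input=len(df))
    keep = np.ones(len(df), dtype=bool)

    if dedup and len(df):
        dup = df.duplicated(
            subset=["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"],
            keep="first",
        ).to_numpy()
        report.n_duplicate = int(dup.sum())
        keep &= ~dup

    if min_mapq is not None and "mapq1" in df.columns and len(df):
        low = (
            (df["mapq1"].to_numpy() < min_mapq)
            | (df["mapq2"].to_numpy() < min_mapq)
        )
        report.n_low_mapq = int((low & keep).sum())
        keep &= ~low

    if fragments is not None and max_frag_distance is not None and len(df):
        far = np.zeros(len(df), dtype=bool)
        for side in ("1", "2"):
            chroms = df[f"chrom{side}"].to_numpy()
            pos = df[f"pos{side}"].to_numpy()
            for chrom in np.unique(chroms):
                sel = chroms == chrom
                boundaries = np.concatenate(
                    [fragments.starts(chrom), fragments.ends(chrom)[-1:]]
                )
                d = _distance_to_cut(pos[sel], boundaries)
                far[sel] |= d > max_frag_distance
        report.n_far_from_cut = int((far & keep).sum())
        keep &= ~far

    out = df.loc[keep].reset_index(drop=True)
    report.n_retained = len(out)
    return out, report


def bin_contacts(df: pd.DataFrame, scheme: BinScheme) -> ContactMatrix:
    """Aggregate pairs into a symmetric binned contact matrix.

    Each pair increments exactly one upper-triangle cell, so the matrix
    grand total equals the number of pairs.
    """
    n = scheme.n_bins_total
    if len(df) == 0:
        return ContactMatrix(scheme, sp.csr_matrix((n, n)))
    gi = np.empty(len(df), dtype=np.int64)
    gj = np.empty(len(df), dtype=np.int64)
    for side, out in (("1", gi), ("2", gj)):
        chroms = df[f"chrom{side}"].to_numpy()
        pos = df[f"pos{side}"].to_numpy()
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            out[sel] = scheme.bin_of(str(chrom), pos[sel])
    lo = np.minimum(gi, gj)
    hi = np.maximum(gi, gj)
    upper = sp.coo_matrix(
        (np.ones(len(df)), (lo, hi)), shape=(n, n)
    ).tocsr()
    return ContactMatrix(scheme, upper)


def _window_fragments(
    fragments: FragmentMap, window: GenomicInterval
) -> np.ndarray:
    """Indices of fragments fully inside the window."""
    if window.chrom not in fragments.genome:
        raise GenomeError(f"window chromosome {window.chrom!r} not in map")
    starts = fragments.starts(window.chrom)
    ends = fragments.ends(window.chrom)
    lo = int(np.searchsorted(starts, window.start, side="left"))
    hi = int(np.searchsorted(ends, window.end, side="right"))
    return np.arange(lo, hi)


def fragment_link_counts(
    df: pd.DataFrame,
    fragments: FragmentMap,
    window_a: GenomicInterval,
    window_b: GenomicInterval,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-fragment counts of pairs linking two windows.

    Returns ``(counts_a, counts_b, frag_idx_a, frag_idx_b)`` where the
    count vectors are indexed over fragments fully inside each window and
    the index arrays give the corresponding fragment indices in the map.
    Every linking pair contributes once to each side.
    """
    if window_a.chrom == window_b.chrom and window_a.overlaps(window_b):
        raise PairsError("link windows must be disjoint")
    idx_a = _window_fragments(fragments, window_a)
    idx_b = _window_fragments(fragments, window_b)

    def _in(side: str, w: GenomicInterval) -> np.ndarray:
        return (
            (df[f"chrom{side}"].to_numpy() == w.chrom)
            & (df[f"pos{side}"].to_numpy() >= w.start)
            & (df[f"pos{side}"].to_numpy() < w.end)
        )

    linking = (_in("1", window_a) & _in("2", window_b)) | (
        _in("1", window_b) & _in("2", window_a)
    )
    sub = df.loc[linking]

    counts_a = np.zeros(len(idx_a), dtype=np.int64)
    counts_b = np.zeros(len(idx_b), dtype=np.int64)
    for w, idx, counts in ((window_a, idx_a, counts_a), (window_b, idx_b, counts_b)):
        if len(idx) == 0:
            continue
        starts = fragments.starts(w.chrom)[idx]
        f_lo, f_hi = starts[0], fragments.ends(w.chrom)[idx[-1]]
        for side in ("1", "2"):
            sel = (
                (sub[f"chrom{side}"].to_numpy() == w.chrom)
                & (sub[f"pos{side}"].to_numpy() >= w.start)
                & (sub[f"pos{side}"].to_numpy() < w.end)
            )
            pos = sub[f"pos{side}"].to_numpy()[sel]
            pos = pos[(pos >= f_lo) & (pos < f_hi)]
            local = np.searchsorted(starts, pos, side="right") - 1
            np.add.at(counts, local, 1)
    return counts_a, counts_b, idx_a, idx_b
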