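"""Fragment input, genome binning and sparse count-matrix construction.

Single-cell ATAC-seq fragment files are BED-like TSVs (chrom, start, end,
barcode[, count]) in 0-based half-open coordinates.  The genome is tiled
into fixed-width bins and every fragment is assigned to the single bin
containing its midpoint, so each fragment contributes to exactly one bin.
Per-(bin, barcode) entries may be capped to damp PCR/mapping artifacts;
barcode quality filtering always uses the *uncapped* per-barcode fragment
totals, which are carried alongside the matrix.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSet",
    "BinIndex",
    "CountMatrix",
    "read_fragments",
    "write_fragments",
    "read_chrom_sizes",
    "make_bins",
    "count_matrix",
    "filter_barcodes",
    "filter_regions_and_cells",
    "collapse_by_group",
    "save_counts",
    "load_counts",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


@dataclass
class FragmentSet:
    """Collection of sequencing fragments with cell barcodes.

    ``data`` has columns chrom, start, end, barcode, count (count defaults
    to 1 per fragment record).  Records need not be sorted.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"fragment table missing columns: {missing}")
        if len(self.data):
            if (self.data["start"] < 0).any():
                raise ValueError("fragment start < 0")
            if (self.data["end"] <= self.data["start"]).any():
                raise ValueError("fragment end <= start")
            if (self.data["count"] <= 0).any():
                raise ValueError("fragment count must be positive")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def records(self):
        """Iterate fragments as (chrom, start, end, barcode, count) tuples."""
        return list(self.data[FRAGMENT_COLUMNS].itertuples(index=False, name=None))

    @property
    def total_count(self) -> int:
        return int(self.data["count"].sum())


def _open_text(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fragments(path, dialect: str = "auto") -> FragmentSet:
    """Read a 4- or 5-column BED-like fragment file (optionally gzipped).

    Parameters
    ----------
    path : str or Path
        Tab-separated file; lines starting with ``#`` are skipped.
    dialect : {"auto", "4-column", "5-column"}
        With "4-column" every record gets count 1; with "5-column" the fifth
        field is parsed as a positive integer count; "auto" accepts both.
    """
    if dialect not in ("auto", "4-column", "5-column"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    chroms, starts, ends, barcodes, counts = [], [], [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "4-column" and len(fields) < 4:
                raise ValueError(f"expected 4 columns at line {lineno}")
            if dialect == "5-column" and len(fields) < 5:
                raise ValueError(f"expected 5 columns at line {lineno}")
            if len(fields) < 4:
                raise ValueError(f"expected at least 4 columns at line {lineno}")
            chrom, start_s, end_s, barcode = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"non-integer coordinates at line {lineno}: {line!r}"
                ) from exc
            if end <= start:
                raise ValueError(f"end <= start at line {lineno}")
            if start < 0:
                raise ValueError(f"negative start at line {lineno}")
            if not chrom:
                raise ValueError(f"empty chromosome at line {lineno}")
            count = 1
            if dialect != "4-column" and len(fields) >= 5:
                try:
                    count = int(fields[4])
                except ValueError as exc:
                    raise ValueError(f"non-integer count at line {lineno}") from exc
                if count <= 0:
                    raise ValueError(f"non-positive count at line {lineno}")
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            barcodes.append(barcode)
            counts.append(count)
    data = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
            "barcode": barcodes,
            "count": np.asarray(counts, dtype=np.int64),
        }
    )
    return FragmentSet(data)


def write_fragments(frags: FragmentSet, path) -> None:
    """Write fragments as 5-column TSV (gzipped if path ends in .gz)."""
    with _open_text(path, "wt") as fh:
        for chrom, start, end, barcode, count in frags.data[
            FRAGMENT_COLUMNS
        ].itertuples(index=False, name=None):
            fh.write(f"{chrom}\t{start}\t{end}\t{barcode}\t{count}\n")


def read_chrom_sizes(path) -> dict:
    """Read a 2-column (chrom, size) TSV into an ordered dict."""
    sizes = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"expected 2 columns at line {lineno}")
            chrom, size = fields[0], int(fields[1])
            if chrom in sizes:
                raise ValueError(f"duplicate chromosome {chrom!r} at line {lineno}")
            if size <= 0:
                raise ValueError(f"non-positive size at line {lineno}")
            sizes[chrom] = size
    return sizes


@dataclass
class BinIndex:
    """Fixed-width tiling of a genome, 0-based half-open bins.

    Bin k of a chromosome is [k*binsize, min((k+1)*binsize, size)); the last
    bin of each chromosome may be shorter than ``binsize``.  Bin order is
    chromosome order of the input table, then position.
    """

    binsize: int
    chrom_order: list
    chrom_sizes: dict
    offsets: dict = field(init=False)

    def __post_init__(self) -> None:
        if self.binsize < 1:
            raise ValueError("binsize must be >= 1")
        if len(set(self.chrom_order)) != len(self.chrom_order):
            raise ValueError("duplicate chromosome name")
        self.offsets = {}
        off = 0
        for chrom in self.chrom_order:
            size = self.chrom_sizes[chrom]
            if size <= 0:
                raise ValueError(f"non-positive size for {chrom}")
            self.offsets[chrom] = off
            off += -(-size // self.binsize)
        self._n_bins = off

    @property
    def n_bins(self) -> int:
        return self._n_bins

    def n_bins_of(self, chrom) -> int:
        return -(-self.chrom_sizes[chrom] // self.binsize)

    def chrom_slices(self):
        """Yield (chrom, slice) pairs covering the bin axis in order."""
        for chrom in self.chrom_order:
            off = self.offsets[chrom]
            yield chrom, slice(off, off + self.n_bins_of(chrom))

    def bin_index(self, chrom, pos) -> int:
        """Global bin index containing position ``pos`` on ``chrom``."""
        if pos < 0 or pos >= self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self.offsets[chrom] + pos // self.binsize

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chrom_order:
            size = self.chrom_sizes[chrom]
            starts = np.arange(0, size, self.binsize, dtype=np.int64)
            ends = np.minimum(starts + self.binsize, size)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def to_bed(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "BinIndex":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])
        widths = (df["end"] - df["start"]).to_numpy()
        binsize = int(widths.max())
        chrom_order = list(dict.fromkeys(df["chrom"]))
        chrom_sizes = {c: int(df.loc[df["chrom"] == c, "end"].max()) for c in chrom_order}
        return cls(binsize=binsize, chrom_order=chrom_order, chrom_sizes=chrom_sizes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinIndex)
            and self.binsize == other.binsize
            and self.chrom_order == other.chrom_order
            and self.chrom_sizes == other.chrom_sizes
        )


def make_bins(chrom_sizes, binsize: int) -> BinIndex:
    """Tile the genome given a {chrom: size} table (dict or 2-col DataFrame)."""
    if isinstance(chrom_sizes, pd.DataFrame):
        names = chrom_sizes.iloc[:, 0].tolist()
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome name")
        chrom_sizes = dict(zip(names, chrom_sizes.iloc[:, 1].astype(int)))
    return BinIndex(binsize=binsize, chrom_order=list(chrom_sizes), chrom_sizes=dict(chrom_sizes))


@dataclass
class CountMatrix:
    """Sparse bins x tracks integer count matrix with genome metadata.

    ``track_totals`` are the uncapped per-track fragment totals computed
    before any cap was applied (barcode quality filtering is defined on
    these, not on capped entries).  ``bin_ids`` is None when the rows cover
    the full genome tiling, or a global-bin-index array for a region subset.
    """

    values: sp.csr_matrix
    bins: BinIndex
    tracks: list
    track_totals: np.ndarray
    cap: int | None = None
    n_dropped: int = 0
    bin_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.track_totals = np.asarray(self.track_totals)
        if self.values.shape[1] != len(self.tracks):
            raise ValueError("track dimension mismatch")
        if len(self.track_totals) != len(self.tracks):
            raise ValueError("track_totals dimension mismatch")
        n_rows = self.bins.n_bins if self.bin_ids is None else len(self.bin_ids)
        if self.values.shape[0] != n_rows:
            raise ValueError("bin dimension mismatch")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts")
        if self.cap is not None and self.values.nnz and self.values.data.max() > self.cap:
            raise ValueError("entries exceed declared cap")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_tracks(self) -> int:
        return self.values.shape[1]

    @property
    def bin_totals(self) -> np.ndarray:
        """Per-bin summed (possibly capped) counts r_i."""
        return np.asarray(self.values.sum(axis=1)).ravel()

    @property
    def entry_track_totals(self) -> np.ndarray:
        """Per-track sums of the stored (possibly capped) entries."""
        return np.asarray(self.values.sum(axis=0)).ravel()


def count_matrix(frags: FragmentSet, bins: BinIndex, cap: int | None = None) -> CountMatrix:
    """Build the bins x barcodes matrix by fragment-midpoint assignment.

    Each fragment is assigned to the bin containing floor((start+end)/2);
    per-(bin, barcode) sums are then trimmed to at most ``cap`` when given.
    Fragments on chromosomes absent from ``bins`` (or whose midpoint falls
    past the chromosome end) are dropped and tallied in ``n_dropped``.
    """
    df = frags.data
    chrom_ok = df["chrom"].isin(bins.chrom_sizes.keys()).to_numpy()
    mid = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)
    sizes = df["chrom"].map(bins.chrom_sizes).to_numpy()
    with np.errstate(invalid="ignore"):
        in_range = chrom_ok & (mid < np.where(np.isnan(sizes.astype(float)), 0, sizes))
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.warning("dropped %d fragments outside the bin index", n_dropped)
    kept = df.loc[in_range]
    mid = mid[in_range]
    offs = kept["chrom"].map(bins.offsets).to_numpy(dtype=np.int64)
    bin_idx = offs + mid // bins.binsize
    # sorted track order makes the matrix invariant to input record order
    barcodes = np.sort(pd.unique(kept["barcode"]))
    code = pd.Categorical(kept["barcode"], categories=barcodes).codes
    counts = kept["count"].to_numpy()
    mat = sp.coo_matrix(
        (counts, (bin_idx, code)), shape=(bins.n_bins, len(barcodes)), dtype=np.int64
    ).tocsr()
    mat.sum_duplicates()
    track_totals = np.bincount(code, weights=counts, minlength=len(barcodes)).astype(np.int64)
    if cap is not None:
        mat.data = np.minimum(mat.data, cap)
    return CountMatrix(
        values=mat,
        bins=bins,
        tracks=list(barcodes),
        track_totals=track_totals,
        cap=cap,
        n_dropped=n_dropped,
    )


def filter_barcodes(cm: CountMatrix, min_fragments: int, max_fragments: int) -> CountMatrix:
    """Keep tracks whose uncapped fragment total lies in [min, max], order preserved."""
    if min_fragments > max_fragments:
        raise ValueError("min_fragments > max_fragments")
    keep = (cm.track_totals >= min_fragments) & (cm.track_totals <= max_fragments)
    if not keep.any():
        raise ValueError("no barcodes survive filtering")
    idx = np.flatnonzero(keep)
    return replace(
        cm,
        values=cm.values[:, idx],
        tracks=[cm.tracks[i] for i in idx],
        track_totals=cm.track_totals[idx],
    )


def filter_regions_and_cells(
    cm: CountMatrix, min_region_count: int, min_cell_count: int
) -> CountMatrix:
    """Filter a region-of-interest matrix: regions first, then cells.

    Regions (rows) with cross-cell sum >= ``min_region_count`` are kept,
    then cells (columns) with cross-region sum >= ``min_cell_count`` over
    the kept regions.
    """
    row_sum = np.asarray(cm.values.sum(axis=1)).ravel()
    rows = np.flatnonzero(row_sum >= min_region_count)
    if rows.size == 0:
        raise ValueError("no regions survive filtering")
    sub = cm.values[rows, :]
    col_sum = np.asarray(sub.sum(axis=0)).ravel()
    cols = np.flatnonzero(col_sum >= min_cell_count)
    if cols.size == 0:
        raise ValueError("no cells survive filtering")
    old_ids = cm.bin_ids if cm.bin_ids is not None else np.arange(cm.n_bins)
    return replace(
        cm,
        values=sub[:, cols],
        tracks=[cm.tracks[i] for i in cols],
        track_totals=cm.track_totals[cols],
        bin_ids=old_ids[rows],
    )


def collapse_by_group(cm: CountMatrix, labels: dict) -> CountMatrix:
    """Sum cell tracks into pseudo-bulk group tracks (sorted group names).

    Barcodes without a label are dropped with a warning, as are groups left
    without members.  Totals over labeled barcodes are conserved.
    """
    if not labels:
        raise ValueError("empty label map")
    if cm.cap is not None:
        warnings.warn(
            "collapsing a capped matrix: pseudo-bulk sums are sums of capped entries"
        )
    unlabeled = [t for t in cm.tracks if t not in labels]
    if unlabeled:
        warnings.warn(f"dropping {len(unlabeled)} unlabeled barcodes")
    groups = sorted({labels[t] for t in cm.tracks if t in labels})
    empty = sorted({g for g in set(labels.values()) if g not in groups})
    if empty:
        warnings.warn(f"groups with no member barcodes dropped: {empty}")
    gidx = {g: i for i, g in enumerate(groups)}
    if not groups:
        raise ValueError("no labeled barcodes to collapse")
    # bins x cells @ cells x groups indicator
    ind = sp.lil_matrix((cm.n_tracks, len(groups)), dtype=np.int64)
    for j, t in enumerate(cm.tracks):
        if t in labels:
            ind[j, gidx[labels[t]]] = 1
    collapsed = (cm.values @ ind.tocsr()).tocsr()
    totals = np.zeros(len(groups), dtype=np.int64)
    for j, t in enumerate(cm.tracks):
        if t in labels:
            totals[gidx[labels[t]]] += cm.track_totals[j]
    return replace(
        cm, values=collapsed, tracks=groups, track_totals=totals, cap=None
    )


def save_counts(cm: CountMatrix, prefix) -> None:
    """Persist as MTX plus sidecar TSVs (bin BED, track table)."""
    prefix = str(prefix)
    scipy.io.mmwrite(prefix + ".mtx", cm.values)
    cm.bins.to_bed(prefix + ".bins.bed")
    pd.DataFrame({"track": cm.tracks, "total": cm.track_totals}).to_csv(
        prefix + ".tracks.tsv", sep="\t", index=False
    )
    meta = {"cap": "" if cm.cap is None else str(cm.cap), "n_dropped": str(cm.n_dropped)}
    with open(prefix + ".meta.tsv", "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}\t{v}\n")


def load_counts(prefix) -> CountMatrix:
    prefix = str(prefix)
    values = sp.csr_matrix(scipy.io.mmread(prefix + ".mtx")).astype(np.int64)
    bins = BinIndex.from_bed(prefix + ".bins.bed")
    tracks_df = pd.read_csv(prefix + ".tracks.tsv", sep="\t")
    meta = {}
    with open(prefix + ".meta.tsv") as fh:
        for line in fh:
            k, _, v = line.rstrip("\n").partition("\t")
            meta[k] = v
    cap = int(meta["cap"]) if meta.get("cap") else None
    return CountMatrix(
        values=values,
        bins=bins,
        tracks=tracks_df["track"].astype(str).tolist(),
        track_totals=tracks_df["total"].to_numpy(dtype=np.int64),
        cap=cap,
        n_dropped=int(meta.get("n_dropped", 0)),
    )
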