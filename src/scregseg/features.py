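"""Feature identification (fi): rare foreground states and their regions.

After segmenting per-cell accessibility, states covering at most a small
fraction of the genome (default 1.5%) are the informative "foreground";
high-confidence bins of those states (posterior >= 0.9) are exported as
regions, with genomically bookended same-state bins merged.  Cell-state
association scores log(a_ij / b_i) compare how often a cell's accessible
bins carry state i against the state's genome-wide frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import CountMatrix
from .hmm import Segmentation

__all__ = [
    "RegionSet",
    "CellStateAssociation",
    "state_frequencies",
    "select_foreground_states",
    "extract_regions",
    "cell_state_association",
]


@dataclass
class RegionSet:
    """Genomic intervals with state labels, sorted by genome position.

    Columns: chrom, start, end, state, posterior (max over merged bins),
    score (round(1000*posterior), BED convention).
    """

    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    def to_bed(self, path) -> None:
        out = self.data[["chrom", "start", "end"]].copy()
        out["name"] = "state_" + self.data["state"].astype(str)
        out["score"] = self.data["score"]
        out["strand"] = "."
        out.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        state = df["name"].str.replace("state_", "", regex=False).astype(int)
        return cls(
            pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "start": df["start"],
                    "end": df["end"],
                    "state": state,
                    "posterior": df["score"] / 1000.0,
                    "score": df["score"],
                }
            )
        )

    @property
    def total_length(self) -> int:
        return int((self.data["end"] - self.data["start"]).sum())


def state_frequencies(seg: Segmentation) -> np.ndarray:
    """Genome-wide Viterbi state frequencies b_i (fractions of bins)."""
    counts = np.bincount(seg.state_call, minlength=seg.n_states)
    return counts / seg.n_bins


def select_foreground_states(seg: Segmentation, max_fraction: float = 0.015) -> np.ndarray:
    """States whose calls cover at most ``max_fraction`` of the genome.

    The comparison is inclusive ("at most 1.5%").  An empty result is
    returned with a warning rather than raising.
    """
    b = state_frequencies(seg)
    states = np.flatnonzero(b <= max_fraction)
    if states.size == 0:
        warnings.warn("no state covers <= %.3f of the genome; empty foreground" % max_fraction)
    return states


def extract_regions(
    seg: Segmentation, states, min_posterior: float = 0.9
) -> RegionSet:
    """High-confidence regions of the given states, bookended-merged.

    Bins whose called state is in ``states`` and whose posterior for that
    call is at least ``min_posterior`` are kept; runs of genomically
    adjacent kept bins of the same state (end == next start, same
    chromosome) are merged into one interval whose posterior is the maximum
    over its member bins.
    """
    states = set(int(s) for s in np.atleast_1d(states))
    df = seg.bins.to_dataframe()
    keep = np.isin(seg.state_call, list(states)) & (seg.max_posterior >= min_posterior)
    rows = []
    idx = np.flatnonzero(keep)
    calls = seg.state_call
    mp = seg.max_posterior
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    cur = None  # [chrom, start, end, state, posterior]
    for i in idx:
        if (
            cur is not None
            and chroms[i] == cur[0]
            and starts[i] == cur[2]
            and calls[i] == cur[3]
        ):
            cur[2] = ends[i]
            cur[4] = max(cur[4], mp[i])
        else:
            if cur is not None:
                rows.append(tuple(cur))
            cur = [chroms[i], starts[i], ends[i], int(calls[i]), float(mp[i])]
    if cur is not None:
        rows.append(tuple(cur))
    data = pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "posterior"])
    data["score"] = np.round(1000 * data["posterior"]).astype(int) if len(data) else pd.Series(dtype=int)
    return RegionSet(data)


@dataclass
class CellStateAssociation:
    """Observed state frequencies per cell vs genome-wide frequencies.

    ``a`` is states x cells with columns summing to 1 for cells with at
    least one accessible bin; ``b`` are the genome-wide state frequencies;
    ``logratio`` is log(a/b) with a == 0 reported as NaN so heatmaps stay
    renderable (and undefined all-zero cells flagged).
    """

    a: pd.DataFrame  # states x cells
    b: np.ndarray
    logratio: pd.DataFrame
    undefined_cells: list


def cell_state_association(seg: Segmentation, cm: CountMatrix) -> CellStateAssociation:
    """Fraction of each cell's accessible bins carried by each state.

    A bin is "accessible in cell j" iff its count is > 0.  a_ij is the
    fraction of cell j's accessible bins whose Viterbi call is state i;
    the association score is log(a_ij / b_i) (natural log).
    """
    if cm.n_bins != seg.n_bins:
        raise ValueError("segmentation and count matrix cover different bins")
    S = seg.n_states
    X = cm.values.tocsc()
    a = np.zeros((S, cm.n_tracks))
    undefined = []
    calls = seg.state_call
    for j in range(cm.n_tracks):
        rows = X.indices[X.indptr[j] : X.indptr[j + 1]]
        rows = rows[X.data[X.indptr[j] : X.indptr[j + 1]] > 0]
        if rows.size == 0:
            undefined.append(cm.tracks[j])
            a[:, j] = np.nan
            continue
        a[:, j] = np.bincount(calls[rows], minlength=S) / rows.size
    b = state_frequencies(seg)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.log(a / b[:, None])
    lr[a == 0] = np.nan
    cols = list(cm.tracks)
    index = [f"state_{s}" for s in range(S)]
    return CellStateAssociation(
        a=pd.DataFrame(a, index=index, columns=cols),
        b=b,
        logratio=pd.DataFrame(lr, index=index, columns=cols),
        undefined_cells=undefined,
    )
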