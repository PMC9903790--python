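"""Program identification (pi): regulatory programs from pseudo-bulk tracks.

Cluster-collapsed accessibility at 500 bp resolution is segmented with the
same Dirichlet-multinomial HMM (default 30 states, 100 iterations, 7
restarts); the state-cluster association log(Pcs / Pb) contrasts the share
of a state's reads coming from each cluster with the cluster's overall
read share, so states accessible in one or several cell types stand out
against depth differences between clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import CountMatrix
from .hmm import Segmentation
from .model import DirichletMultinomialHMM, DMHMMResults

__all__ = ["StateClusterAssociation", "run_pi", "state_cluster_association", "plot_association"]


@dataclass
class StateClusterAssociation:
    """Per-state coverage profile over clusters vs background coverage.

    ``Pcs`` rows (states) are distributions over clusters: the share of
    state s's reads contributed by cluster c.  ``Pb`` is the background
    read share per cluster.  ``logratio`` = log(Pcs/Pb), with zero-read
    cells reported as NaN and states without any reads flagged.
    """

    Pcs: pd.DataFrame  # states x clusters
    Pb: np.ndarray
    logratio: pd.DataFrame
    undefined_states: list


def run_pi(
    cluster_cm: CountMatrix,
    n_states: int = 30,
    n_iter: int = 100,
    n_restarts: int = 7,
    seed: int = 0,
    alpha_update: str = "fixedpoint",
) -> tuple[DMHMMResults, Segmentation]:
    """Fit and decode the pseudo-bulk segmentation (program identification).

    Defaults follow the program-identification configuration: 30 states,
    100 Baum-Welch iterations, 7 random restarts, best log-likelihood kept.
    """
    model = DirichletMultinomialHMM(cluster_cm, n_states=n_states, alpha_update=alpha_update)
    res = model.fit(n_iter=n_iter, n_restarts=n_restarts, seed=seed)
    return res, res.decode()


def state_cluster_association(
    seg: Segmentation, cluster_cm: CountMatrix, use_expected: bool = False
) -> StateClusterAssociation:
    """log(Pcs / Pb) association between states and clusters.

    With ``use_expected=False`` (default) reads-in-(cluster, state) are
    tabulated over Viterbi-called bins, which is reproducible from the
    state-call BED plus the matrix alone.  ``use_expected=True`` weights
    bins by their posterior state probabilities instead (expected
    sufficient statistics).
    """
    if cluster_cm.n_bins != seg.n_bins:
        raise ValueError("segmentation and count matrix cover different bins")
    S = seg.n_states
    X = cluster_cm.values.tocsr()
    if use_expected:
        reads = seg.posteriors.T @ X  # states x clusters
        reads = np.asarray(reads)
    else:
        onehot = np.zeros((seg.n_bins, S))
        onehot[np.arange(seg.n_bins), seg.state_call] = 1.0
        reads = np.asarray(onehot.T @ X)
    per_state = reads.sum(axis=1)
    total = reads.sum()
    if total <= 0:
        raise ValueError("count matrix has no reads")
    Pb = reads.sum(axis=0) / total
    undefined = [int(s) for s in np.flatnonzero(per_state == 0)]
    with np.errstate(divide="ignore", invalid="ignore"):
        Pcs = reads / per_state[:, None]
        lr = np.log(Pcs / Pb[None, :])
    lr[Pcs == 0] = np.nan
    index = [f"state_{s}" for s in range(S)]
    cols = list(cluster_cm.tracks)
    return StateClusterAssociation(
        Pcs=pd.DataFrame(Pcs, index=index, columns=cols),
        Pb=Pb,
        logratio=pd.DataFrame(lr, index=index, columns=cols),
        undefined_states=undefined,
    )


def plot_association(assoc, path) -> None:
    """Heatmap of an association logratio table (fi or pi) to a PNG."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    lr = assoc.logratio
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * lr.shape[1]), max(3, 0.25 * lr.shape[0]))
    )
    im = ax.imshow(np.nan_to_num(lr.to_numpy(), nan=np.nanmin(lr.to_numpy()) if np.isfinite(lr.to_numpy()).any() else 0.0), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(lr.shape[1]), lr.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(lr.shape[0]), lr.index, fontsize=7)
    ax.set_xlabel("cluster")
    ax.set_ylabel("state")
    fig.colorbar(im, ax=ax, label="log association")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
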