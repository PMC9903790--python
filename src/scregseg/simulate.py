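"""Synthetic scATAC-seq data with known ground truth.

The generator follows the model's own generative assumptions: a hidden
state path over genome bins drawn from a sticky Markov chain, per-bin
fragment totals drawn from a state-dependent Poisson depth distribution,
and allocation of those fragments to cells by a Dirichlet-multinomial
whose concentration vector encodes which cell clusters a state is
accessible in.  Rare "regulatory" states are accessible in a subset of
clusters at higher depth; broad background states cover most of the
genome.  Fragment files, chromosome sizes, cluster labels, gene
annotations and chromatin-state tracks are emitted in the same plain-text
formats the rest of the package consumes, together with a GroundTruth
object sufficient to score recovery exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import FragmentSet, make_bins, write_fragments

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_dataset",
    "simulate_annotation",
    "simulate_condition_labels",
    "write_dataset",
]


@dataclass
class SimConfig:
    """Study conditions of the synthetic benchmark.

    Defaults describe a 2 Mb mini-genome (2 chromosomes x 1 Mb) tiled at
    1 kb into 2,000 bins, 200 cells in 4 equal clusters, and three
    accessibility states: a rarer regulatory-like state accessible in two
    clusters at elevated depth, a broad state open in all cells, and a
    broad state open in the other two clusters.  Depth means are fragments
    per bin summed across all cells.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    binsize: int = 1000
    n_states: int = 3
    n_cells: int = 200
    n_clusters: int = 4
    # long-run state frequencies (fractions of bins)
    state_freq: tuple = (0.10, 0.45, 0.45)
    # per-state self-transition probability; off-diagonal mass goes to the
    # other states in proportion to their frequency
    self_transition: tuple = (0.8, 0.97, 0.97)
    # clusters in which each state is accessible (None = all clusters)
    state_clusters: tuple = ((0, 1), None, (2, 3))
    # mean fragments per bin (across cells) for each state
    depth_mean: tuple = (90.0, 30.0, 30.0)
    # Dirichlet concentration per accessible / inaccessible cell; moderate
    # within-state overdispersion, so that states are identifiable as
    # distinct allocation profiles (the model's own generative premise)
    alpha_on: float = 3.0
    alpha_off: float = 0.02
    fragment_length: int = 150
    # "markov": path drawn from the chain; "planted": states flagged as
    # planted are carved in as segments totalling exactly round(freq * B)
    # bins over a Markov background path
    path_mode: str = "markov"
    planted_states: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        if len(self.state_freq) != self.n_states:
            raise ValueError("state_freq length mismatch")
        if len(self.self_transition) != self.n_states:
            raise ValueError("self_transition length mismatch")
        if len(self.state_clusters) != self.n_states:
            raise ValueError("state_clusters length mismatch")
        if len(self.depth_mean) != self.n_states:
            raise ValueError("depth_mean length mismatch")
        if not np.isclose(sum(self.state_freq), 1.0):
            raise ValueError("state_freq must sum to 1")
        if any(f <= 0 for f in self.state_freq):
            raise ValueError("state frequencies must be positive")
        if any(not (0 <= s <= 1) for s in self.self_transition):
            raise ValueError("self_transition must lie in [0, 1]")
        if self.path_mode not in ("markov", "planted"):
            raise ValueError(f"unknown path_mode: {self.path_mode!r}")
        if self.path_mode == "planted" and not self.planted_states:
            raise ValueError("planted mode requires planted_states")


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the simulation exactly."""

    state_path: np.ndarray  # per global bin
    alpha: np.ndarray  # (n_states, n_cells) allocation concentrations
    cell_clusters: dict  # barcode -> cluster name
    transition: np.ndarray
    config: SimConfig
    gene_sets: dict = field(default_factory=dict)  # set name -> target state
    condition_labels: dict = field(default_factory=dict)


def _transition_matrix(cfg: SimConfig) -> np.ndarray:
    """Sticky chain T_ij = s_i I + (1 - s_i) f_j with stationary pi_j
    proportional to f_j / (1 - s_j); f is solved so that pi equals the
    requested state frequencies."""
    freq = np.asarray(cfg.state_freq, dtype=float)
    s = np.asarray(cfg.self_transition, dtype=float)
    f = freq * (1.0 - s)
    if f.sum() == 0:
        return np.eye(cfg.n_states)
    f = f / f.sum()
    T = np.outer(1.0 - s, f)
    T[np.diag_indices_from(T)] += s
    T = T / T.sum(axis=1, keepdims=True)
    return T


def _sample_path(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    bins = make_bins({f"chr{i+1}": cfg.chrom_length for i in range(cfg.n_chroms)}, cfg.binsize)
    T = _transition_matrix(cfg)
    freq = np.asarray(cfg.state_freq, dtype=float)
    path = np.empty(bins.n_bins, dtype=int)
    for _, sl in bins.chrom_slices():
        n = sl.stop - sl.start
        seq = np.empty(n, dtype=int)
        seq[0] = rng.choice(cfg.n_states, p=freq)
        for t in range(1, n):
            seq[t] = rng.choice(cfg.n_states, p=T[seq[t - 1]])
        path[sl] = seq
    if cfg.path_mode == "planted":
        planted = list(cfg.planted_states)
        bg = [s for s in range(cfg.n_states) if s not in planted]
        # resample background-only path, then carve in planted segments with
        # exact total occupancy round(freq * B)
        bg_freq = freq[bg] / freq[bg].sum()
        for _, sl in bins.chrom_slices():
            n = sl.stop - sl.start
            Tb = T[np.ix_(bg, bg)]
            Tb = Tb / Tb.sum(axis=1, keepdims=True)
            seq = np.empty(n, dtype=int)
            seq[0] = rng.choice(len(bg), p=bg_freq)
            for t in range(1, n):
                seq[t] = rng.choice(len(bg), p=Tb[seq[t - 1]])
            path[sl] = np.asarray(bg)[seq]
        for s in planted:
            target = int(round(freq[s] * bins.n_bins))
            seg_len = max(1, int(round(1.0 / max(1.0 - cfg.self_transition[s], 1e-6))))
            placed = 0
            guard = 0
            while placed < target and guard < 100000:
                guard += 1
                L = min(seg_len, target - placed)
                start = int(rng.integers(0, bins.n_bins - L + 1))
                window = path[start : start + L]
                if np.isin(window, planted).any():
                    continue
                window[:] = s
                placed += L
    return path


def _state_alpha(cfg: SimConfig, cell_cluster_idx: np.ndarray) -> np.ndarray:
    alpha = np.full((cfg.n_states, cfg.n_cells), cfg.alpha_off)
    for s, clusters in enumerate(cfg.state_clusters):
        if clusters is None:
            alpha[s, :] = cfg.alpha_on
        else:
            member = np.isin(cell_cluster_idx, list(clusters))
            alpha[s, member] = cfg.alpha_on
    return alpha


def simulate_dataset(cfg: SimConfig):
    """Draw one synthetic dataset.

    Returns (FragmentSet, chrom_sizes dict, labels dict, GroundTruth); the
    whole draw is reproducible from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chrom_sizes = {f"chr{i+1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    bins = make_bins(chrom_sizes, cfg.binsize)
    path = _sample_path(cfg, rng)
    barcodes = [f"CELL{i:05d}" for i in range(cfg.n_cells)]
    cluster_idx = np.arange(cfg.n_cells) % cfg.n_clusters
    rng.shuffle(cluster_idx)
    labels = {bc: f"cluster{cluster_idx[i]}" for i, bc in enumerate(barcodes)}
    alpha = _state_alpha(cfg, cluster_idx)
    half = cfg.fragment_length // 2
    chroms_out, starts_out, ends_out, bcs_out = [], [], [], []
    depth = np.asarray(cfg.depth_mean, dtype=float)
    for chrom, sl in bins.chrom_slices():
        size = chrom_sizes[chrom]
        for local, gbin in enumerate(range(sl.start, sl.stop)):
            s = path[gbin]
            n = int(rng.poisson(depth[s]))
            if n == 0:
                continue
            p = rng.dirichlet(alpha[s])
            if not np.all(np.isfinite(p)):
                p = alpha[s] / alpha[s].sum()
            cell_counts = rng.multinomial(n, p)
            bin_start = local * cfg.binsize
            bin_end = min(bin_start + cfg.binsize, size)
            lo = max(bin_start, half)
            hi = min(bin_end, size - half)
            if lo >= hi:
                lo, hi = bin_start, bin_end
            for cell in np.flatnonzero(cell_counts):
                k = cell_counts[cell]
                mids = rng.integers(lo, hi, size=k)
                for m in mids:
                    start = max(0, int(m) - half)
                    end = min(size, int(m) + half)
                    chroms_out.append(chrom)
                    starts_out.append(start)
                    ends_out.append(end)
                    bcs_out.append(barcodes[cell])
    frags = FragmentSet(
        pd.DataFrame(
            {
                "chrom": chroms_out,
                "start": np.asarray(starts_out, dtype=np.int64),
                "end": np.asarray(ends_out, dtype=np.int64),
                "barcode": bcs_out,
                "count": np.ones(len(bcs_out), dtype=np.int64),
            }
        )
    )
    truth = GroundTruth(
        state_path=path,
        alpha=alpha,
        cell_clusters=labels,
        transition=_transition_matrix(cfg),
        config=cfg,
    )
    return frags, chrom_sizes, labels, truth


def simulate_annotation(
    cfg: SimConfig,
    truth: GroundTruth,
    n_set_genes: int = 20,
    n_decoy_genes: int = 100,
    placement_rate: float = 1.0,
    gene_body_length: int = 2000,
    flank: int = 10_000,
    target_states: tuple | None = None,
    state_labels: dict | None = None,
    seed: int | None = None,
):
    """Plant gene sets near chosen states and derive a chromatin-state BED.

    For each target state a gene set is created whose TSSs are placed
    within ``flank`` bp of a bin of that state with probability
    ``placement_rate`` (uniformly otherwise); decoy genes are placed
    uniformly.  The chromatin-state annotation maps accessibility states
    to labels (default: planted/first state "enhancer_like", the rest
    "background").  Returns (GeneAnnotation, state annotation DataFrame).
    """
    from .enrichment import GeneAnnotation

    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    chrom_sizes = {f"chr{i+1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    bins = make_bins(chrom_sizes, cfg.binsize)
    if target_states is None:
        target_states = cfg.planted_states or (0,)
    tss_rows = []
    sets = {}

    def _bin_location(gbin):
        for chrom, sl in bins.chrom_slices():
            if sl.start <= gbin < sl.stop:
                local = gbin - sl.start
                return chrom, local * cfg.binsize
        raise IndexError(gbin)

    gid = 0
    for s in target_states:
        name = f"set_state{s}"
        members = []
        target_bins = np.flatnonzero(truth.state_path == s)
        for _ in range(n_set_genes):
            gene = f"gene{gid:05d}"
            gid += 1
            if target_bins.size and rng.random() < placement_rate:
                gbin = int(rng.choice(target_bins))
                chrom, bstart = _bin_location(gbin)
                offset = int(rng.integers(-flank + cfg.binsize, flank - cfg.binsize))
                pos = int(np.clip(bstart + cfg.binsize // 2 + offset, 0, chrom_sizes[chrom] - 1))
            else:
                chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
                pos = int(rng.integers(0, chrom_sizes[chrom]))
            tss_rows.append((chrom, pos, gene, "+"))
            members.append(gene)
        sets[name] = members
        truth.gene_sets[name] = int(s)
    for _ in range(n_decoy_genes):
        gene = f"gene{gid:05d}"
        gid += 1
        chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
        pos = int(rng.integers(0, chrom_sizes[chrom]))
        tss_rows.append((chrom, pos, gene, "+"))
    tss = pd.DataFrame(tss_rows, columns=["chrom", "pos", "gene", "strand"])
    gene_body = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": tss["pos"],
            "end": np.minimum(
                tss["pos"] + gene_body_length,
                tss["chrom"].map(chrom_sizes),
            ),
            "gene": tss["gene"],
        }
    )
    ann = GeneAnnotation(tss=tss, gene_body=gene_body, gene_sets=sets)
    if state_labels is None:
        state_labels = {s: "enhancer_like" for s in target_states}
    rows = []
    for chrom, sl in bins.chrom_slices():
        for local, gbin in enumerate(range(sl.start, sl.stop)):
            label = state_labels.get(int(truth.state_path[gbin]), "background")
            start = local * cfg.binsize
            end = min(start + cfg.binsize, chrom_sizes[chrom])
            rows.append((chrom, start, end, label))
    state_bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    return ann, state_bed


def simulate_condition_labels(
    cluster_sizes: dict,
    base_fraction: float = 0.42,
    effects: dict | None = None,
    seed: int = 0,
):
    """Split cluster cell counts into condition/reference with planted effects.

    Each cluster's condition count is Binomial(n, fraction) with fraction
    ``base_fraction`` unless overridden in ``effects``.  Returns two dicts
    (condition counts, reference counts) keyed by cluster.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    cond, ref = {}, {}
    for cluster, n in cluster_sizes.items():
        frac = effects.get(cluster, base_fraction)
        k = int(rng.binomial(n, frac))
        cond[cluster] = k
        ref[cluster] = int(n) - k
    return cond, ref


def write_dataset(outdir, frags, chrom_sizes, labels, truth: GroundTruth) -> None:
    """Write the standard input files for the rest of the pipeline."""
    os.makedirs(outdir, exist_ok=True)
    write_fragments(frags, os.path.join(outdir, "fragments.tsv"))
    with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    with open(os.path.join(outdir, "labels.tsv"), "w") as fh:
        for bc, lab in labels.items():
            fh.write(f"{bc}\t{lab}\n")
    np.savetxt(os.path.join(outdir, "true_states.txt"), truth.state_path, fmt="%d")
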