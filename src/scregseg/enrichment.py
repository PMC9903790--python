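"""Downstream statistics for segmentations and region sets.

Covers nearest-TSS assignment of regions to genes, hypergeometric gene-set
enrichment, stationary-distribution-based state enrichment around gene
sets, marker-gene log-ratio scores, Shannon-entropy cell-type specificity,
exact binomial cell-composition tests, and classification of regions
against an external genome-wide chromatin-state annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hmm import Segmentation

__all__ = [
    "GeneAnnotation",
    "EntropyResult",
    "nearest_tss",
    "hypergeom_enrichment",
    "geneset_enrichment",
    "tss_windows",
    "feature_enrichment_score",
    "marker_gene_logratio",
    "shannon_entropy",
    "composition_binomial_test",
    "classify_region_by_state_coverage",
    "classify_regions",
    "state_coverage",
]


@dataclass
class GeneAnnotation:
    """TSS positions, gene bodies and gene-set membership.

    ``tss``: DataFrame (chrom, pos, gene, strand); ``gene_body``: DataFrame
    (chrom, start, end, gene); ``gene_sets``: {set name: [gene ids]}.
    Set members absent from the annotation are dropped with a warning.
    """

    tss: pd.DataFrame
    gene_body: pd.DataFrame
    gene_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tss["gene"].duplicated().any():
            raise ValueError("duplicate gene ids in TSS table")
        known = set(self.tss["gene"])
        cleaned = {}
        for name, genes in self.gene_sets.items():
            missing = [g for g in genes if g not in known]
            if missing:
                warnings.warn(
                    f"gene set {name!r}: dropping {len(missing)} unknown genes"
                )
            cleaned[name] = [g for g in genes if g in known]
        self.gene_sets = cleaned

    @classmethod
    def from_files(cls, tss_bed, gene_body_bed, gene_sets_tsv=None) -> "GeneAnnotation":
        """Load from BED6 TSS / gene-body files and a 2-column (set, gene) TSV.

        The TSS position is the interval start for '+' (or '.') strand
        genes and end-1 for '-' strand genes.
        """
        names = ["chrom", "start", "end", "name", "score", "strand"]
        tss = pd.read_csv(tss_bed, sep="\t", header=None, names=names)
        pos = np.where(tss["strand"] == "-", tss["end"] - 1, tss["start"])
        tss_df = pd.DataFrame(
            {"chrom": tss["chrom"], "pos": pos, "gene": tss["name"], "strand": tss["strand"]}
        )
        gb = pd.read_csv(gene_body_bed, sep="\t", header=None, names=names)
        gb_df = pd.DataFrame(
            {"chrom": gb["chrom"], "start": gb["start"], "end": gb["end"], "gene": gb["name"]}
        )
        sets = {}
        if gene_sets_tsv is not None:
            gs = pd.read_csv(gene_sets_tsv, sep="\t", header=None, names=["set", "gene"])
            for name, grp in gs.groupby("set"):
                sets[name] = grp["gene"].tolist()
        return cls(tss=tss_df, gene_body=gb_df, gene_sets=sets)


def nearest_tss(regions, ann: GeneAnnotation) -> pd.DataFrame:
    """Map each region to the nearest TSS on the same chromosome.

    Distance is |region midpoint - TSS position|; equidistant ties go to
    the lower-coordinate TSS.  Regions on chromosomes without any TSS are
    returned with gene NaN and flagged in the ``assigned`` column.
    """
    rdf = regions.data if hasattr(regions, "data") else regions
    out_gene, out_dist, out_ok = [], [], []
    tss_by_chrom = {}
    for chrom, grp in ann.tss.groupby("chrom"):
        grp = grp.sort_values(["pos", "gene"], kind="mergesort")
        tss_by_chrom[chrom] = (grp["pos"].to_numpy(), grp["gene"].to_numpy())
    for chrom, start, end in rdf[["chrom", "start", "end"]].itertuples(index=False, name=None):
        mid = (start + end) // 2
        if chrom not in tss_by_chrom:
            out_gene.append(np.nan)
            out_dist.append(np.nan)
            out_ok.append(False)
            continue
        pos, genes = tss_by_chrom[chrom]
        i = np.searchsorted(pos, mid)
        cands = [j for j in (i - 1, i) if 0 <= j < len(pos)]
        # lower coordinate wins ties: candidates are already coordinate-sorted
        best = min(cands, key=lambda j: (abs(int(pos[j]) - mid), int(pos[j])))
        out_gene.append(genes[best])
        out_dist.append(abs(int(pos[best]) - mid))
        out_ok.append(True)
    res = rdf[["chrom", "start", "end"]].copy()
    res["gene"] = out_gene
    res["distance"] = out_dist
    res["assigned"] = out_ok
    return res


def hypergeom_enrichment(k: int, n: int, N: int, M: int) -> float:
    """Upper-tail hypergeometric enrichment p-value P(X >= k).

    Drawing N genes (those hit by regions) from a universe of M genes of
    which n belong to the gene set, the p-value is the probability of
    observing at least the k set genes actually hit.
    """
    for name, v in (("k", k), ("n", n), ("N", N), ("M", M)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if n > M or N > M:
        raise ValueError("n and N must not exceed M")
    if k > min(n, N):
        raise ValueError("k must not exceed min(n, N)")
    return float(stats.hypergeom.sf(k - 1, M, n, N))


def geneset_enrichment(regions, ann: GeneAnnotation, universe_size: int | None = None) -> pd.DataFrame:
    """Hypergeometric enrichment of gene sets among region-associated genes.

    Regions are mapped to their nearest TSS, each gene counted once; for
    every gene set the test asks whether the unique region-associated genes
    over-represent the set.  Raw p-values are primary; Benjamini-Hochberg
    FDR is reported alongside.
    """
    mapped = nearest_tss(regions, ann)
    hit_genes = set(mapped.loc[mapped["assigned"], "gene"])
    M = universe_size if universe_size is not None else len(ann.tss)
    N = len(hit_genes)
    rows = []
    for name, genes in ann.gene_sets.items():
        n = len(genes)
        k = len(hit_genes & set(genes))
        p = hypergeom_enrichment(k, n, N, M)
        rows.append((name, k, n, N, M, p))
    df = pd.DataFrame(rows, columns=["gene_set", "k", "n", "N", "M", "pvalue"])
    if len(df):
        df["fdr"] = stats.false_discovery_control(df["pvalue"], method="bh")
    return df


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly-overlapping intervals, per chromosome."""
    pieces = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        starts, ends = [], []
        for s, e in grp[["start", "end"]].itertuples(index=False, name=None):
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        pieces.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(pieces, ignore_index=True) if pieces else df


def tss_windows(ann: GeneAnnotation, genes, flank: int = 10_000, chrom_sizes: dict | None = None) -> pd.DataFrame:
    """TSS +/- ``flank`` windows for the given genes, clipped at chromosome ends."""
    sub = ann.tss[ann.tss["gene"].isin(set(genes))]
    df = pd.DataFrame(
        {
            "chrom": sub["chrom"],
            "start": np.maximum(sub["pos"] - flank, 0),
            "end": sub["pos"] + flank,
        }
    )
    if chrom_sizes:
        df["end"] = [
            min(e, chrom_sizes.get(c, e)) for c, e in zip(df["chrom"], df["end"])
        ]
    return df.reset_index(drop=True)


def _bins_in_windows(seg: Segmentation, windows: pd.DataFrame) -> np.ndarray:
    """Global indices of bins whose midpoint lies in the merged windows."""
    merged = _merge_intervals(windows[["chrom", "start", "end"]])
    hits = []
    for chrom, sl in seg.bins.chrom_slices():
        w = merged[merged["chrom"] == chrom]
        if w.empty:
            continue
        n = sl.stop - sl.start
        starts = np.arange(n, dtype=np.int64) * seg.bins.binsize
        ends = np.minimum(starts + seg.bins.binsize, seg.bins.chrom_sizes[chrom])
        mids = (starts + ends) // 2
        ws = w["start"].to_numpy()
        we = w["end"].to_numpy()
        # window index whose start is at or before each midpoint
        j = np.searchsorted(ws, mids, side="right") - 1
        inside = (j >= 0) & (mids < we[np.clip(j, 0, len(we) - 1)])
        hits.append(np.flatnonzero(inside) + sl.start)
    return np.concatenate(hits) if hits else np.array([], dtype=int)


def feature_enrichment_score(
    seg: Segmentation, target_regions: pd.DataFrame, p: np.ndarray
) -> pd.DataFrame:
    """Squared-ratio enrichment of state calls inside target regions.

    o_i counts state-i bin calls inside the (merged) target regions, N is
    the total number of calls inside them, and e_i = N * p_i is the count
    expected from the stationary distribution.  The score is
    ((o_i - e_i)^2 / e_i^2) when o_i > e_i and 0 otherwise; e_i == 0 with
    o_i > 0 yields +inf and is flagged.
    """
    p = np.asarray(p, dtype=float)
    idx = _bins_in_windows(seg, target_regions)
    o = np.bincount(seg.state_call[idx], minlength=seg.n_states).astype(float)
    N = float(idx.size)
    e = N * p
    score = np.zeros(seg.n_states)
    flagged = np.zeros(seg.n_states, dtype=bool)
    above = o > e
    with np.errstate(divide="ignore", invalid="ignore"):
        sc = (o - e) ** 2 / e**2
    score[above] = sc[above]
    bad = (e == 0) & (o > 0)
    score[bad] = np.inf
    flagged[bad] = True
    return pd.DataFrame(
        {
            "state": np.arange(seg.n_states),
            "observed": o.astype(int),
            "expected": e,
            "score": score,
            "flagged": flagged,
        }
    )


def marker_gene_logratio(
    seg: Segmentation,
    ann: GeneAnnotation,
    state: int,
    p: np.ndarray | None = None,
    flank: int = 10_000,
) -> pd.DataFrame:
    """Rank genes by excess of state calls over their gene body +/- flank.

    Per gene the score is log((o / N_g) / p_state): the fraction of calls
    in the window carrying the state over the fraction expected from the
    stationary distribution.  Genes whose window contains no bins are
    skipped with a flag; windows without any call of the state score -inf.
    """
    if p is None:
        raise ValueError("stationary distribution p must be provided")
    p = np.asarray(p, dtype=float)
    ps = p[state]
    rows = []
    skipped = []
    for chrom, start, end, gene in ann.gene_body[
        ["chrom", "start", "end", "gene"]
    ].itertuples(index=False, name=None):
        win = pd.DataFrame(
            {
                "chrom": [chrom],
                "start": [max(0, start - flank)],
                "end": [min(end + flank, seg.bins.chrom_sizes.get(chrom, end + flank))],
            }
        )
        if chrom not in seg.bins.chrom_sizes:
            skipped.append(gene)
            continue
        idx = _bins_in_windows(seg, win)
        if idx.size == 0:
            skipped.append(gene)
            continue
        o = int((seg.state_call[idx] == state).sum())
        with np.errstate(divide="ignore"):
            score = float(np.log((o / idx.size) / ps))
        rows.append((gene, o, idx.size, score))
    df = pd.DataFrame(rows, columns=["gene", "observed", "n_bins", "score"])
    df = df.sort_values("score", ascending=False).reset_index(drop=True)
    df.attrs["skipped_genes"] = skipped
    return df


@dataclass
class EntropyResult:
    """Per-region Shannon entropy (bits) and the probability vectors used."""

    entropy: np.ndarray  # (n_regions,)
    probs: np.ndarray  # (n_regions, n_clusters)

    def __post_init__(self) -> None:
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("probability rows must sum to 1")


def shannon_entropy(region_by_cluster_counts, pseudocount: int = 1) -> EntropyResult:
    """Cell-type specificity of regions as Shannon entropy over clusters.

    A pseudocount is added to every entry, each cluster column is divided
    by its total (depth normalization), each region row is renormalized to
    a probability vector p, and SE = -sum_i p_i log2 p_i is reported in
    bits.  Low entropy marks cluster-specific regions, high entropy
    constitutive ones.
    """
    X = np.asarray(region_by_cluster_counts, dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    X = X + pseudocount
    X = X / X.sum(axis=0, keepdims=True)
    p = X / X.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    se = -terms.sum(axis=1)
    return EntropyResult(entropy=se, probs=p)


def composition_binomial_test(
    counts_condition, counts_reference
) -> pd.DataFrame:
    """Per-cluster exact binomial test of condition-cell over/under-representation.

    The success probability p0 is the condition share of all cells pooled
    over clusters; per cluster, the two-sided exact test asks whether the
    cluster's condition count out of its total deviates from p0.  Reports
    the cluster fraction, direction, raw p-value (primary) and BH FDR.
    """
    cond = pd.Series(counts_condition, dtype=int)
    ref = pd.Series(counts_reference, dtype=int)
    ref = ref.reindex(cond.index, fill_value=0)
    total_cond = int(cond.sum())
    total = total_cond + int(ref.sum())
    if total <= 0:
        raise ValueError("no cells")
    p0 = total_cond / total
    rows = []
    for cluster in cond.index:
        k = int(cond[cluster])
        nn = k + int(ref[cluster])
        if nn == 0:
            rows.append((cluster, k, nn, np.nan, np.nan, "empty", True))
            continue
        pv = stats.binomtest(k, nn, p0, alternative="two-sided").pvalue
        frac = k / nn
        direction = "enriched" if frac > p0 else ("depleted" if frac < p0 else "neutral")
        rows.append((cluster, k, nn, frac, float(pv), direction, False))
    df = pd.DataFrame(
        rows,
        columns=["cluster", "n_condition", "n_total", "fraction", "pvalue", "direction", "skipped"],
    )
    df.attrs["p0"] = p0
    df.attrs["total_cells"] = total
    ok = ~df["skipped"]
    if ok.any():
        df.loc[ok, "fdr"] = stats.false_discovery_control(df.loc[ok, "pvalue"], method="bh")
    return df


def classify_region_by_state_coverage(
    region_coverage,
    regionset_coverage,
    genome_probs,
    region_length: float | None = None,
):
    """Classify one region by its chromatin-state coverage profile.

    The observed coverage of state s in the region is normalized by the
    state's total coverage over the whole region set; the expected share is
    the genome-wide state probability times the region length, normalized
    by the region set's total covered length.  The score is the log of
    observed over expected share and the label the argmax (ties: lowest
    state index, flagged).  Regions with no coverage at all are labelled
    "background".
    """
    cov = np.asarray(region_coverage, dtype=float)
    tot = np.asarray(regionset_coverage, dtype=float)
    gp = np.asarray(genome_probs, dtype=float)
    if cov.shape != tot.shape or cov.shape != gp.shape:
        raise ValueError("dimension mismatch")
    if cov.sum() == 0:
        return "background", np.full(cov.shape, np.nan), True
    if region_length is None:
        region_length = float(cov.sum())
    T = tot.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        observed_share = cov / tot
        expected_share = gp * region_length / T
        score = np.log(observed_share / expected_share)
    score[~np.isfinite(score)] = -np.inf
    best = float(score.max())
    winners = np.flatnonzero(score == best)
    tie = winners.size > 1
    return int(winners[0]), score, tie


def state_coverage(regions: pd.DataFrame, states: pd.DataFrame, state_names=None):
    """Per-region per-state coverage (bp) of a state annotation BED.

    ``states`` has columns chrom, start, end, state.  Returns (matrix
    n_regions x n_states, state name list).
    """
    if state_names is None:
        state_names = sorted(states["state"].unique())
    sidx = {s: i for i, s in enumerate(state_names)}
    out = np.zeros((len(regions), len(state_names)))
    by_chrom = {c: g.sort_values("start") for c, g in states.groupby("chrom")}
    for r, (chrom, start, end) in enumerate(
        regions[["chrom", "start", "end"]].itertuples(index=False, name=None)
    ):
        g = by_chrom.get(chrom)
        if g is None:
            continue
        ss = g["start"].to_numpy()
        se = g["end"].to_numpy()
        lab = g["state"].to_numpy()
        ov = np.minimum(se, end) - np.maximum(ss, start)
        for j in np.flatnonzero(ov > 0):
            out[r, sidx[lab[j]]] += ov[j]
    return out, list(state_names)


def classify_regions(
    regions: pd.DataFrame,
    state_annotation: pd.DataFrame,
    genome_probs=None,
    genome_size: int | None = None,
) -> pd.DataFrame:
    """Classify every region against a genome-wide state annotation.

    ``genome_probs`` defaults to each state's share of annotated bp
    (optionally of ``genome_size`` bp).  Returns the label per region plus
    the per-state scores.
    """
    rdf = regions.data if hasattr(regions, "data") else regions
    cov, names = state_coverage(rdf, state_annotation)
    if genome_probs is None:
        lengths = (
            state_annotation.assign(length=lambda d: d["end"] - d["start"])
            .groupby("state")["length"]
            .sum()
            .reindex(names, fill_value=0)
            .to_numpy(dtype=float)
        )
        denom = genome_size if genome_size is not None else lengths.sum()
        genome_probs = lengths / denom
    else:
        genome_probs = np.asarray(genome_probs, dtype=float)
    totals = cov.sum(axis=0)
    lengths = (rdf["end"] - rdf["start"]).to_numpy(dtype=float)
    labels, ties = [], []
    scores = np.full((len(rdf), len(names)), np.nan)
    for r in range(len(rdf)):
        label, score, tie = classify_region_by_state_coverage(
            cov[r], totals, genome_probs, region_length=lengths[r]
        )
        labels.append("background" if label == "background" else names[label])
        ties.append(tie)
        finite = np.isfinite(score)
        scores[r, finite] = score[finite]
    out = rdf[["chrom", "start", "end"]].copy()
    out["label"] = labels
    out["tie"] = ties
    for j, s in enumerate(names):
        out[f"score_{s}"] = scores[:, j]
    return out
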