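"""Dirichlet-multinomial hidden Markov model over genome bins.

Each HMM state s carries a concentration vector alpha_s over tracks (cells
or pseudo-bulk clusters); the emission probability of a bin's count vector
x with total n = sum(x) is the Dirichlet-multinomial pmf conditioned on n,

    P(x | alpha_s) = C(n; x) * G(A)/G(n+A) * prod_c G(x_c+a_c)/G(a_c),

with A = sum(alpha_s) and G the gamma function.  Conditioning on n makes
sequencing depth a nuisance: states are distinguished by their cross-track
allocation profile, not by coverage.  Each chromosome is an independent
sequence sharing parameters; transitions never span chromosome boundaries.
Bins with zero total count have pmf 1 under every state and inherit their
state from neighbouring context through the transition matrix.

Fitting is Baum-Welch (EM): the E-step runs a scaled forward-backward pass
per chromosome; the M-step re-estimates transitions/initial probabilities
from expected counts and updates alpha per state either by Minka's
fixed-point iteration on posterior-weighted counts (default) or by moment
matching.  Multiple random restarts guard against poor local optima.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import digamma, gammaln

from .fragments import BinIndex, CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "HMMParams",
    "Segmentation",
    "emission_logpmf",
    "emission_loglik_matrix",
    "forward_backward",
    "viterbi",
    "decode",
    "baum_welch_fit",
    "fit_with_restarts",
    "stationary_distribution",
]

ALPHA_FLOOR = 1e-6


@dataclass
class HMMParams:
    """Parameters of a fitted (or hand-set) Dirichlet-multinomial HMM."""

    alpha: np.ndarray  # (n_states, n_tracks), all > 0
    transition: np.ndarray  # (n_states, n_states), row-stochastic
    initial: np.ndarray  # (n_states,)
    seed: int | None = None
    n_iter_run: int = 0
    loglik_trace: list = field(default_factory=list)
    restart_logliks: list = field(default_factory=list)
    tracks: list | None = None

    def __post_init__(self) -> None:
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        self.transition = np.atleast_2d(np.asarray(self.transition, dtype=float))
        self.initial = np.asarray(self.initial, dtype=float).ravel()
        self.validate()

    @property
    def n_states(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_tracks(self) -> int:
        return self.alpha.shape[1]

    @property
    def loglik(self) -> float | None:
        return self.loglik_trace[-1] if self.loglik_trace else None

    def validate(self) -> None:
        if (self.alpha <= 0).any():
            raise ValueError("alpha must be strictly positive")
        if self.transition.shape != (self.n_states, self.n_states):
            raise ValueError("transition shape mismatch")
        if self.initial.shape != (self.n_states,):
            raise ValueError("initial shape mismatch")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-10):
            raise ValueError("initial must sum to 1")

    def emission_means(self) -> np.ndarray:
        """Per-state expected track allocation alpha_s / sum(alpha_s)."""
        return self.alpha / self.alpha.sum(axis=1, keepdims=True)

    def save(self, path) -> None:
        payload = {
            "alpha": self.alpha.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "seed": self.seed,
            "n_iter_run": self.n_iter_run,
            "loglik_trace": list(map(float, self.loglik_trace)),
            "restart_logliks": list(map(float, self.restart_logliks)),
            "tracks": self.tracks,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "HMMParams":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            alpha=np.asarray(payload["alpha"]),
            transition=np.asarray(payload["transition"]),
            initial=np.asarray(payload["initial"]),
            seed=payload.get("seed"),
            n_iter_run=payload.get("n_iter_run", 0),
            loglik_trace=payload.get("loglik_trace", []),
            restart_logliks=payload.get("restart_logliks", []),
            tracks=payload.get("tracks"),
        )


@dataclass
class Segmentation:
    """Per-bin Viterbi state calls plus forward-backward posteriors."""

    state_call: np.ndarray  # (n_bins,) int
    posteriors: np.ndarray  # (n_bins, n_states)
    loglik: float
    bins: BinIndex

    def __post_init__(self) -> None:
        self.state_call = np.asarray(self.state_call, dtype=int)
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        if self.state_call.shape[0] != self.posteriors.shape[0]:
            raise ValueError("state_call/posteriors length mismatch")
        sums = self.posteriors.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("posteriors must sum to 1 per bin")

    @property
    def n_states(self) -> int:
        return self.posteriors.shape[1]

    @property
    def n_bins(self) -> int:
        return self.state_call.shape[0]

    @property
    def max_posterior(self) -> np.ndarray:
        """Posterior probability of the called state, per bin."""
        return self.posteriors[np.arange(self.n_bins), self.state_call]

    def to_dataframe(self):
        df = self.bins.to_dataframe()
        df["state"] = self.state_call
        df["max_posterior"] = self.max_posterior
        return df

    def to_bed(self, path) -> None:
        """Per-bin BED6-like output: name=state_K, score=1000*max posterior."""
        df = self.to_dataframe()
        out = df[["chrom", "start", "end"]].copy()
        out["name"] = "state_" + df["state"].astype(str)
        out["score"] = np.round(1000 * df["max_posterior"]).astype(int)
        out["strand"] = "."
        out.to_csv(path, sep="\t", header=False, index=False)


def emission_logpmf(alpha_s, x) -> float:
    """Log Dirichlet-multinomial pmf of count vector ``x`` given ``alpha_s``."""
    alpha_s = np.asarray(alpha_s, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if (alpha_s <= 0).any():
        raise ValueError("alpha must be strictly positive")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if alpha_s.shape != x.shape:
        raise ValueError("dimension mismatch")
    n = x.sum()
    A = alpha_s.sum()
    return float(
        gammaln(n + 1)
        - gammaln(x + 1).sum()
        + gammaln(A)
        - gammaln(n + A)
        + (gammaln(x + alpha_s) - gammaln(alpha_s)).sum()
    )


def emission_loglik_matrix(params: HMMParams, cm: CountMatrix) -> np.ndarray:
    """(n_bins, n_states) log emission likelihoods, sparse-aware.

    Only nonzero entries contribute to the per-track gamma terms because
    gammaln(0 + a) - gammaln(a) = 0.
    """
    if params.n_tracks != cm.n_tracks:
        raise ValueError("track dimensionality of model and matrix differ")
    X = cm.values.tocsr()
    n = np.asarray(X.sum(axis=1)).ravel().astype(float)
    A = params.alpha.sum(axis=1)
    const = gammaln(n + 1)
    if X.nnz:
        fact = sp.csr_matrix(
            (gammaln(X.data + 1.0), X.indices, X.indptr), shape=X.shape
        )
        const = const - np.asarray(fact.sum(axis=1)).ravel()
    out = np.empty((X.shape[0], params.n_states))
    for s in range(params.n_states):
        a = params.alpha[s]
        out[:, s] = const + gammaln(A[s]) - gammaln(n + A[s])
        if X.nnz:
            vals = gammaln(X.data + a[X.indices]) - gammaln(a[X.indices])
            term = sp.csr_matrix((vals, X.indices, X.indptr), shape=X.shape)
            out[:, s] += np.asarray(term.sum(axis=1)).ravel()
    return out


def _scaled_forward_backward(logB, transition, initial):
    """Scaled forward-backward on one sequence.

    Returns (gamma, xi_sum, loglik) where gamma is (T, S) posteriors and
    xi_sum the (S, S) expected transition counts summed over t.
    """
    T, S = logB.shape
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])  # rowwise-rescaled likelihoods
    alpha = np.empty((T, S))
    c = np.empty(T)
    a = initial * B[0]
    c[0] = a.sum()
    if c[0] <= 0 or not np.isfinite(c[0]):
        raise FloatingPointError("non-finite forward pass at bin 0")
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transition) * B[t]
        c[t] = a.sum()
        if c[t] <= 0 or not np.isfinite(c[t]):
            raise FloatingPointError(f"non-finite forward pass at bin {t}")
        alpha[t] = a / c[t]
    beta = np.empty((T, S))
    beta[-1] = 1.0
    xi_sum = np.zeros((S, S))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        xi_sum += np.outer(alpha[t], bb / c[t + 1]) * transition
        beta[t] = (transition @ bb) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + shift.sum())
    return gamma, xi_sum, loglik


def forward_backward(params: HMMParams, cm: CountMatrix):
    """Posterior decoding over all chromosomes.

    Each chromosome is an independent sequence re-initialized from
    ``params.initial``.  Returns (Segmentation-without-viterbi posteriors as
    ndarray, expected transition counts, per-chromosome-start gammas,
    total loglik); use :func:`decode` for a full :class:`Segmentation`.
    """
    logB = emission_loglik_matrix(params, cm)
    S = params.n_states
    gamma = np.empty((cm.n_bins, S))
    xi_sum = np.zeros((S, S))
    start_gammas = []
    loglik = 0.0
    for chrom, sl in cm.bins.chrom_slices():
        try:
            g, xi, ll = _scaled_forward_backward(
                logB[sl], params.transition, params.initial
            )
        except FloatingPointError as exc:
            raise FloatingPointError(f"{exc} on {chrom}") from exc
        gamma[sl] = g
        xi_sum += xi
        start_gammas.append(g[0])
        loglik += ll
    return gamma, xi_sum, np.asarray(start_gammas), loglik


def viterbi(params: HMMParams, cm: CountMatrix) -> np.ndarray:
    """Most probable state path per chromosome (ties: lowest state index)."""
    logB = emission_loglik_matrix(params, cm)
    with np.errstate(divide="ignore"):
        logT = np.log(params.transition)
        logI = np.log(params.initial)
    path = np.empty(cm.n_bins, dtype=int)
    for _, sl in cm.bins.chrom_slices():
        lb = logB[sl]
        T = lb.shape[0]
        delta = logI + lb[0]
        back = np.empty((T, params.n_states), dtype=int)
        for t in range(1, T):
            cand = delta[:, None] + logT  # prev x next
            back[t] = np.argmax(cand, axis=0)  # first max = lowest index
            delta = cand[back[t], np.arange(params.n_states)] + lb[t]
        p = np.empty(T, dtype=int)
        p[-1] = int(np.argmax(delta))
        for t in range(T - 2, -1, -1):
            p[t] = back[t + 1][p[t + 1]]
        path[sl] = p
    return path


def decode(params: HMMParams, cm: CountMatrix) -> Segmentation:
    """Viterbi state calls plus forward-backward posteriors."""
    gamma, _, _, loglik = forward_backward(params, cm)
    path = viterbi(params, cm)
    return Segmentation(state_call=path, posteriors=gamma, loglik=loglik, bins=cm.bins)


def _outlier_weights(cm: CountMatrix, profile: np.ndarray) -> np.ndarray:
    """Sampling weights favouring bins poorly explained by the global profile.

    The per-fragment log-likelihood of every bin under a single global
    Dirichlet-multinomial state is compared with the median; bins falling
    short (concentrated, atypical allocation patterns) receive exponential
    weight.  Used to anchor initial states on rare patterns, in the spirit
    of k-means++ seeding.
    """
    C = cm.n_tracks
    n = np.asarray(cm.values.sum(axis=1)).ravel().astype(float)
    base = HMMParams(alpha=(C * profile)[None, :], transition=[[1.0]], initial=[1.0])
    logB = emission_loglik_matrix(base, cm).ravel()
    rate = logB / np.maximum(n, 1.0)
    covered = n > 0
    if not covered.any():
        return np.zeros_like(n)
    med = np.median(rate[covered])
    deficit = np.maximum(0.0, med - rate) * n
    temp = max(np.percentile(deficit, 95) / 4.0, 1.0)
    w = np.exp(np.minimum(deficit / temp, 50.0))
    w[~covered] = 0.0
    if w.sum() <= 0:
        w = covered.astype(float)
    return w / w.sum()


def _sticky_transition(n_states: int, rng: np.random.Generator) -> np.ndarray:
    transition = np.full((n_states, n_states), 0.1 / n_states) + 0.9 * np.eye(n_states)
    transition += rng.uniform(0, 0.01 / n_states, size=(n_states, n_states))
    return transition / transition.sum(axis=1, keepdims=True)


def _init_params(
    cm: CountMatrix, n_states: int, rng: np.random.Generator, scheme: str = "global"
) -> HMMParams:
    """Random initialization with near-uniform sticky transitions.

    Three seeding schemes for the concentration vectors, cycled across
    restarts because they explore complementary parts of the likelihood
    surface:

    - "global": mildly Gamma-perturbed copies of the global track profile;
    - "sharp": exponentially perturbed copies, giving widely dispersed
      starting profiles that split broad states more readily;
    - "anchored": every state anchored on the smoothed local profile of a
      data bin, chosen k-means++-style — the first anchor is sampled from
      outlier-weighted bins and the rest greedily maximize dissimilarity to
      the anchors already chosen — which seeds rare allocation patterns.
    """
    C = cm.n_tracks
    X = cm.values.tocsr()
    colsum = np.asarray(X.sum(axis=0)).ravel().astype(float)
    profile = (colsum + 1.0) / (colsum.sum() + C)
    alpha = np.empty((n_states, C))
    anchors_done = 0
    if scheme == "anchored" and n_states > 1:
        w = _outlier_weights(cm, profile)
        n_cand = int(min(150, (w > 0).sum()))
        if n_cand >= n_states:
            cand = rng.choice(len(w), size=n_cand, replace=False, p=w)
            profs = np.empty((n_cand, C))
            for j, i in enumerate(cand):
                lo, hi = max(0, int(i) - 1), min(X.shape[0], int(i) + 2)
                v = np.asarray(X[lo:hi].sum(axis=0)).ravel().astype(float)
                profs[j] = v / max(v.sum(), 1.0)
            norms = np.linalg.norm(profs, axis=1) + 1e-12
            chosen = [int(rng.integers(n_cand))]
            sims = np.full(n_cand, -np.inf)
            for _ in range(n_states - 1):
                j = chosen[-1]
                sims = np.maximum(sims, profs @ profs[j] / (norms * norms[j]))
                chosen.append(int(np.argmin(sims)))
            for s, j in enumerate(chosen):
                mix = 0.7 * profs[j] + 0.3 * profile
                perturb = rng.gamma(shape=20.0, scale=0.05, size=C)
                alpha[s] = np.maximum(C * mix * perturb, ALPHA_FLOOR)
            anchors_done = n_states
    for s in range(anchors_done, n_states):
        if scheme == "sharp":
            perturb = rng.gamma(shape=1.0, scale=1.0, size=C)
        else:
            perturb = rng.gamma(shape=5.0, scale=0.2, size=C)
        alpha[s] = np.maximum(C * profile * perturb, ALPHA_FLOOR)
    return HMMParams(
        alpha=alpha,
        transition=_sticky_transition(n_states, rng),
        initial=np.full(n_states, 1.0 / n_states),
    )


def _alpha_fixedpoint(X: sp.csr_matrix, w: np.ndarray, alpha: np.ndarray, n_inner: int = 10):
    """Minka fixed-point update of one state's concentration vector.

    Maximizes the posterior-weighted Dirichlet-multinomial likelihood; each
    step is a bound-maximization step, so the weighted likelihood never
    decreases.  Zero entries contribute nothing (digamma(x+a)-digamma(a)=0
    at x=0), so only nonzeros are touched.
    """
    n = np.asarray(X.sum(axis=1)).ravel().astype(float)
    active = n > 0
    w_act = w[active]
    n_act = n[active]
    if w_act.sum() <= 0:
        return alpha.copy()
    w_nz = w[_row_of(X)]
    for _ in range(n_inner):
        A = alpha.sum()
        vals = w_nz * (digamma(X.data + alpha[X.indices]) - digamma(alpha[X.indices]))
        num = np.bincount(X.indices, weights=vals, minlength=X.shape[1])
        den = float((w_act * (digamma(n_act + A) - digamma(A))).sum())
        if den <= 0:
            break
        new = alpha * num / den
        new = np.maximum(new, ALPHA_FLOOR)
        if np.max(np.abs(new - alpha) / np.maximum(alpha, 1e-12)) < 1e-6:
            alpha = new
            break
        alpha = new
    return alpha


def _row_of(X: sp.csr_matrix) -> np.ndarray:
    """Row index of every stored nonzero of a CSR matrix."""
    return np.repeat(np.arange(X.shape[0]), np.diff(X.indptr))


def _weighted_state_loglik(X: sp.csr_matrix, w: np.ndarray, alpha: np.ndarray) -> float:
    """Posterior-weighted Dirichlet-multinomial log-likelihood of one state
    (dropping the alpha-free multinomial coefficient)."""
    n = np.asarray(X.sum(axis=1)).ravel().astype(float)
    A = alpha.sum()
    per_bin = gammaln(A) - gammaln(n + A)
    if X.nnz:
        vals = gammaln(X.data + alpha[X.indices]) - gammaln(alpha[X.indices])
        term = sp.csr_matrix((vals, X.indices, X.indptr), shape=X.shape)
        per_bin = per_bin + np.asarray(term.sum(axis=1)).ravel()
    return float(w @ per_bin)


def _alpha_moments(X: sp.csr_matrix, w: np.ndarray, alpha: np.ndarray):
    """Moment-matching alpha update, guarded to never decrease the state's
    weighted likelihood (a generalized-EM step).

    Matches the weighted mean allocation and estimates the concentration
    total from the weighted variance of allocation proportions; if the
    candidate scores worse than the current alpha it is rejected.
    """
    n = np.asarray(X.sum(axis=1)).ravel().astype(float)
    active = n > 0
    wsum = float(w[active].sum())
    if wsum <= 0:
        return alpha.copy()
    # weighted mean proportions
    Wn = sp.diags(np.where(active, w / np.maximum(n, 1.0), 0.0))
    mean_p = np.asarray((Wn @ X).sum(axis=0)).ravel() / wsum
    mean_p = np.maximum(mean_p, 1e-12)
    mean_p /= mean_p.sum()
    # weighted second moment of proportions (sparse-aware)
    rows = _row_of(X)
    p2 = np.zeros(X.shape[1])
    scale = np.where(active, w, 0.0) / np.maximum(n, 1.0) ** 2
    np.add.at(p2, X.indices, scale[rows] * X.data.astype(float) ** 2)
    p2 /= wsum
    var_p = np.maximum(p2 - mean_p**2, 1e-12)
    # method-of-moments concentration from the first track with signal
    j = int(np.argmax(mean_p))
    A = mean_p[j] * (1 - mean_p[j]) / var_p[j] - 1.0
    A = float(np.clip(A, 1e-3, 1e6))
    candidate = np.maximum(A * mean_p, ALPHA_FLOOR)
    if _weighted_state_loglik(X, w, candidate) < _weighted_state_loglik(X, w, alpha):
        return alpha.copy()
    return candidate


def baum_welch_fit(
    cm: CountMatrix,
    n_states: int,
    n_iter: int = 300,
    seed: int = 0,
    alpha_update: str = "fixedpoint",
    tol: float = 1e-6,
    init: str = "global",
) -> HMMParams:
    """Fit the model by expectation-maximization from one random start.

    Stops after ``n_iter`` iterations or once the log-likelihood improves by
    less than ``tol * |loglik|``.  ``init`` selects the seeding scheme (see
    :func:`_init_params`).  States whose expected occupancy collapses are
    reinitialized from a perturbed global profile with a warning.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if alpha_update not in ("fixedpoint", "moments"):
        raise ValueError(f"unknown alpha_update: {alpha_update!r}")
    rng = np.random.default_rng(seed)
    if init not in ("global", "sharp", "anchored"):
        raise ValueError(f"unknown init: {init!r}")
    params = _init_params(cm, n_states, rng, scheme=init)
    params.seed = seed
    X = cm.values.tocsr()
    trace = []
    update = _alpha_fixedpoint if alpha_update == "fixedpoint" else _alpha_moments
    for it in range(n_iter):
        gamma, xi_sum, start_gammas, loglik = forward_backward(params, cm)
        trace.append(loglik)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-1]):
            break
        # M-step
        occupancy = gamma.sum(axis=0)
        trans = xi_sum.copy()
        rowsums = trans.sum(axis=1, keepdims=True)
        good = rowsums.ravel() > 0
        trans[good] /= rowsums[good]
        trans[~good] = 1.0 / n_states
        initial = start_gammas.sum(axis=0)
        initial = initial / initial.sum()
        alpha = params.alpha.copy()
        # "zero expected occupancy" in the strict sense: reinitialization is a
        # rescue for numerically dead states, not a pruning heuristic
        low = occupancy < 1e-6
        for s in range(n_states):
            if low[s]:
                logger.warning("state %d occupancy collapsed; reinitializing", s)
                colsum = np.asarray(X.sum(axis=0)).ravel().astype(float)
                profile = (colsum + 1.0) / (colsum.sum() + cm.n_tracks)
                perturb = rng.gamma(shape=5.0, scale=0.2, size=cm.n_tracks)
                alpha[s] = np.maximum(cm.n_tracks * profile * perturb, ALPHA_FLOOR)
            else:
                alpha[s] = update(X, gamma[:, s], params.alpha[s])
        params = HMMParams(
            alpha=alpha, transition=trans, initial=initial, seed=seed
        )
    params.loglik_trace = trace
    params.n_iter_run = len(trace)
    params.tracks = list(cm.tracks)
    return params


def fit_with_restarts(
    cm: CountMatrix,
    n_states: int,
    n_restarts: int = 7,
    n_iter: int = 300,
    seed: int = 0,
    alpha_update: str = "fixedpoint",
    tol: float = 1e-6,
) -> HMMParams:
    """Run Baum-Welch from several random starts, keep the best loglik.

    Restarts cycle through the three seeding schemes (mild global
    perturbation, k-means++-style outlier anchoring, sharp global
    perturbation), so the search explores broad-state splits and
    rare-state seeds alike; the best final log-likelihood decides.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    # first restart uses the seed itself, so n_restarts=1 reduces exactly to
    # baum_welch_fit(seed); further restarts use seeds derived from it
    child_seeds = [seed] + [int(s) for s in rng.integers(0, 2**31 - 1, size=n_restarts - 1)]
    best = None
    logliks = []
    schemes = ("global", "anchored", "sharp")
    for r, cs in enumerate(child_seeds):
        fitted = baum_welch_fit(
            cm,
            n_states,
            n_iter=n_iter,
            seed=int(cs),
            alpha_update=alpha_update,
            tol=tol,
            init=schemes[r % 3],
        )
        logliks.append(fitted.loglik)
        if best is None or fitted.loglik > best.loglik:
            best = fitted
    best.restart_logliks = [float(x) for x in logliks]
    logger.info("restart logliks: %s", best.restart_logliks)
    return best


def stationary_distribution(transition: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Long-run state occupancy p with p = p @ transition, sum(p) = 1.

    Principal left eigenvector via eigen-decomposition with a
    power-iteration fallback; the identity matrix (every distribution
    stationary) returns the uniform distribution with a warning.
    """
    T = np.atleast_2d(np.asarray(transition, dtype=float))
    S = T.shape[0]
    if T.shape != (S, S) or (T < -1e-12).any() or not np.allclose(
        T.sum(axis=1), 1.0, atol=1e-8
    ):
        raise ValueError("transition matrix is not row-stochastic")
    if np.allclose(T, np.eye(S)):
        warnings.warn("identity transition: any distribution is stationary; returning uniform")
        return np.full(S, 1.0 / S)
    vals, vecs = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    p = np.real(vecs[:, idx])
    p = np.abs(p)
    p = p / p.sum()
    if np.max(np.abs(p @ T - p)) > tol:
        # power-iteration fallback
        p = np.full(S, 1.0 / S)
        for _ in range(100000):
            nxt = p @ T
            if np.max(np.abs(nxt - p)) < 1e-14:
                p = nxt
                break
            p = nxt
        p = p / p.sum()
        if np.max(np.abs(p @ T - p)) > tol:
            raise ValueError("failed to find stationary distribution")
    return p
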