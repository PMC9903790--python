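"""Model/Results interface over the Dirichlet-multinomial HMM.

`DirichletMultinomialHMM` is constructed from a :class:`CountMatrix` (or
straight from a fragment file) and `fit()` returns a :class:`DMHMMResults`
object carrying the fitted parameters, restart diagnostics, the decoded
segmentation, and a `summary()` table — the same division of labour as a
statsmodels model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import hmm
from .fragments import CountMatrix, FragmentSet, count_matrix, make_bins, read_fragments

__all__ = ["DirichletMultinomialHMM", "DMHMMResults"]


class DirichletMultinomialHMM:
    """Hidden Markov model with Dirichlet-multinomial emissions over bins.

    Parameters
    ----------
    counts : CountMatrix
        Bins x tracks observation matrix (cells for feature identification,
        pseudo-bulk clusters for program identification).
    n_states : int
        Number of hidden accessibility states.
    alpha_update : {"fixedpoint", "moments"}
        M-step rule for the concentration vectors.
    """

    def __init__(self, counts: CountMatrix, n_states: int, alpha_update: str = "fixedpoint"):
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        self.counts = counts
        self.n_states = n_states
        self.alpha_update = alpha_update

    @classmethod
    def from_fragments(
        cls,
        fragments,
        chrom_sizes: dict,
        n_states: int,
        binsize: int = 1000,
        cap: int | None = 4,
        **kwargs,
    ) -> "DirichletMultinomialHMM":
        """Build the model straight from a fragment file or FragmentSet."""
        if not isinstance(fragments, FragmentSet):
            fragments = read_fragments(fragments)
        bins = make_bins(chrom_sizes, binsize)
        cm = count_matrix(fragments, bins, cap=cap)
        return cls(cm, n_states=n_states, **kwargs)

    def fit(
        self,
        n_iter: int = 300,
        n_restarts: int = 7,
        seed: int = 0,
        tol: float = 1e-6,
    ) -> "DMHMMResults":
        """Baum-Welch with random restarts; keeps the best log-likelihood."""
        params = hmm.fit_with_restarts(
            self.counts,
            self.n_states,
            n_restarts=n_restarts,
            n_iter=n_iter,
            seed=seed,
            alpha_update=self.alpha_update,
            tol=tol,
        )
        return DMHMMResults(self, params)

    def loglike(self, params: hmm.HMMParams) -> float:
        """Data log-likelihood under given parameters."""
        _, _, _, ll = hmm.forward_backward(params, self.counts)
        return ll


class DMHMMResults:
    """Fitted Dirichlet-multinomial HMM: parameters, decoding, diagnostics."""

    def __init__(self, model: DirichletMultinomialHMM, params: hmm.HMMParams):
        self.model = model
        self.params = params
        self._segmentation = None

    @property
    def llf(self) -> float:
        return self.params.loglik

    @property
    def alpha(self) -> np.ndarray:
        return self.params.alpha

    @property
    def transition(self) -> np.ndarray:
        return self.params.transition

    def emission_means(self) -> np.ndarray:
        return self.params.emission_means()

    def stationary_distribution(self) -> np.ndarray:
        return hmm.stationary_distribution(self.params.transition)

    def decode(self) -> hmm.Segmentation:
        """Viterbi state calls plus forward-backward posteriors (cached)."""
        if self._segmentation is None:
            self._segmentation = hmm.decode(self.params, self.model.counts)
        return self._segmentation

    def state_table(self) -> pd.DataFrame:
        """Per-state diagnostics: stationary probability, Viterbi genome
        fraction, mean call confidence, concentration total."""
        seg = self.decode()
        S = self.params.n_states
        frac = np.bincount(seg.state_call, minlength=S) / seg.n_bins
        conf = np.full(S, np.nan)
        for s in range(S):
            mask = seg.state_call == s
            if mask.any():
                conf[s] = seg.max_posterior[mask].mean()
        return pd.DataFrame(
            {
                "state": np.arange(S),
                "stationary_prob": self.stationary_distribution(),
                "genome_fraction": frac,
                "mean_call_posterior": conf,
                "concentration_total": self.params.alpha.sum(axis=1),
            }
        )

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of statsmodels results."""
        cm = self.model.counts
        lines = [
            "Dirichlet-multinomial HMM results",
            "=" * 48,
            f"n_bins:              {cm.n_bins}",
            f"n_tracks:            {cm.n_tracks}",
            f"n_states:            {self.params.n_states}",
            f"log-likelihood:      {self.llf:.4f}",
            f"EM iterations:       {self.params.n_iter_run}",
            f"restarts:            {len(self.params.restart_logliks) or 1}",
        ]
        if self.params.restart_logliks:
            spread = max(self.params.restart_logliks) - min(self.params.restart_logliks)
            lines.append(f"restart llf spread:  {spread:.4f}")
        lines.append("")
        lines.append(self.state_table().to_string(index=False, float_format="%.4f"))
        return "\n".join(lines)

    def save(self, path) -> None:
        self.params.save(path)
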