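"""Recovery metrics for benchmarking fits against simulation ground truth."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

__all__ = ["match_states", "state_call_ari", "emission_mean_tv"]


def match_states(true_path, called_path, n_true: int, n_called: int) -> dict:
    """Optimal fitted-to-true state relabelling by overlap (Hungarian).

    Returns {called state: true state}; with more called than true states
    the surplus states map to their best-overlap true state greedily.
    """
    true_path = np.asarray(true_path)
    called_path = np.asarray(called_path)
    conf = np.zeros((n_called, n_true))
    for c, t in zip(called_path, true_path):
        conf[c, t] += 1
    rows, cols = linear_sum_assignment(-conf)
    mapping = dict(zip(rows.tolist(), cols.tolist()))
    for c in range(n_called):
        if c not in mapping:
            mapping[c] = int(np.argmax(conf[c])) if conf[c].sum() else 0
    return mapping


def state_call_ari(true_path, called_path) -> float:
    """Adjusted Rand index between true and called per-bin state labels."""
    return float(adjusted_rand_score(np.asarray(true_path), np.asarray(called_path)))


def emission_mean_tv(true_alpha, fitted_alpha, mapping: dict) -> float:
    """Mean total-variation distance between matched emission mean profiles."""
    true_alpha = np.asarray(true_alpha, dtype=float)
    fitted_alpha = np.asarray(fitted_alpha, dtype=float)
    tp = true_alpha / true_alpha.sum(axis=1, keepdims=True)
    fp = fitted_alpha / fitted_alpha.sum(axis=1, keepdims=True)
    tvs = [0.5 * np.abs(fp[c] - tp[t]).sum() for c, t in mapping.items()]
    return float(np.mean(tvs))
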