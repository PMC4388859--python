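"""Unsupervised maximum relevance-maximum significance (MRMS) feature selection.

Features are scored by their *energy content*: the mean squared deviation of
all entries of a feature subset from the subset's grand mean,

    E(S) = (1 / (n |S|)) sum_i sum_j (x_ij - xbar)^2 .

A feature's relevance is the energy of the singleton set; its significance
with respect to an already-selected feature is the change in energy when it
joins that feature.  High-frequency (textured) subbands score high, smooth
subbands low, and neither score needs class labels — which is what makes the
criterion usable for unsupervised segmentation.

Selection is greedy: pick the most relevant feature first, then repeatedly
pick the candidate maximizing relevance plus its average significance with
respect to the selected set, after pruning any candidate that is dispensable
(zero significance) with respect to any selected feature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

logger = logging.getLogger(__name__)

__all__ = [
    "energy",
    "relevance",
    "significance",
    "default_m",
    "select",
    "SelectionState",
    "MRMSSelector",
]

#: relative tolerance for "zero significance"; exact zeros are rare in floats
ZERO_SIG_RTOL = 1e-12


def energy(columns: np.ndarray) -> float:
    """Energy content of a feature subset given as an (n, k) column block.

    A 1-D array is treated as a single feature.  Constant blocks have zero
    energy; duplicating a column leaves the energy unchanged.
    """
    columns = np.asarray(columns, float)
    if columns.ndim == 1:
        columns = columns[:, None]
    if columns.size == 0:
        raise ValueError("empty feature subset")
    grand_mean = columns.mean()
    return float(((columns - grand_mean) ** 2).mean())


def relevance(X: np.ndarray, i: int) -> float:
    """Relevance of feature ``i``: the energy of the singleton set."""
    return energy(np.asarray(X, float)[:, i])


def significance(X: np.ndarray, i: int, j: int) -> float:
    """Significance of feature ``j`` w.r.t. the pair ``{i, j}``.

    The change in energy when ``j`` joins ``i``:
    ``E({i, j}) - E({i})``.  Zero means ``j`` is dispensable given ``i``;
    negative values occur when ``j``'s spread is far below ``i``'s.
    """
    if i == j:
        raise ValueError("significance requires two distinct features")
    X = np.asarray(X, float)
    return energy(X[:, [i, j]]) - energy(X[:, i])


def default_m(d: int) -> int:
    """Default number of selected features: ``ceil(sqrt(d))``.

    Maps the seven subbands of a level-2 decomposition to three features.
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    return math.ceil(math.sqrt(d))


@dataclass
class SelectionState:
    """Outcome of the greedy selection, including its full trace."""

    selected: list[int]
    relevance: np.ndarray  # per-feature relevance, length d
    trace: list[dict] = field(default_factory=list)
    pruned: set[int] = field(default_factory=set)


def select(
    X: np.ndarray,
    m: int,
    zero_sig_rtol: float = ZERO_SIG_RTOL,
) -> SelectionState:
    """Greedy MRMS selection of ``m`` features from the columns of ``X``.

    Step 1 picks the argmax of relevance.  Each later step first prunes any
    candidate whose significance is (numerically) zero with respect to *any*
    selected feature, then picks the candidate maximizing

        gamma_j + (1/|S|) * sum_{i in S} sigma_j({i, j}) .

    Significance is used signed.  Ties break toward the lowest feature
    index.  Selection stops at ``|S| = m`` or when the candidate pool
    empties (then ``|S| < m``, logged).
    """
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError(f"expected an (n, d) matrix, got shape {X.shape}")
    n, d = X.shape
    if not 1 <= m <= d:
        raise ValueError(f"m must satisfy 1 <= m <= d={d}, got {m}")

    gamma = np.array([relevance(X, i) for i in range(d)])
    state = SelectionState(selected=[], relevance=gamma)
    candidates = list(range(d))

    first = int(np.argmax(gamma))  # argmax returns the lowest tied index
    state.selected.append(first)
    candidates.remove(first)
    state.trace.append(
        {"step": 1, "chosen": first, "criterion": float(gamma[first]), "pruned": []}
    )

    while len(state.selected) < m and candidates:
        # prune candidates dispensable w.r.t. any selected feature
        pruned_now = []
        for j in list(candidates):
            for i in state.selected:
                sig = significance(X, i, j)
                if abs(sig) <= zero_sig_rtol * max(1.0, gamma[i]):
                    candidates.remove(j)
                    pruned_now.append(j)
                    state.pruned.add(j)
                    break
        if not candidates:
            break
        crit = np.full(d, -np.inf)
        for j in candidates:
            sig_sum = sum(significance(X, i, j) for i in state.selected)
            crit[j] = gamma[j] + sig_sum / len(state.selected)
        chosen = int(np.argmax(crit))
        state.selected.append(chosen)
        candidates.remove(chosen)
        state.trace.append(
            {
                "step": len(state.selected),
                "chosen": chosen,
                "criterion": float(crit[chosen]),
                "pruned": pruned_now,
            }
        )

    if len(state.selected) < m:
        logger.info(
            "candidate pool emptied after %d of %d requested features",
            len(state.selected),
            m,
        )
    return state


class MRMSSelector(TransformerMixin, BaseEstimator):
    """Select features by the energy-based MRMS criterion.

    Parameters
    ----------
    n_features : int or "auto", default="auto"
        Number of features to keep; "auto" uses ``ceil(sqrt(d))``.
    zero_sig_rtol : float, default=1e-12
        Relative tolerance under which a candidate's significance w.r.t. a
        selected feature counts as zero (the candidate is then pruned).

    Attributes
    ----------
    selected_idx_ : list of int
        Indices of the selected features, in selection order.
    relevance_ : ndarray of shape (d,)
        Energy-based relevance of every input feature.
    selection_state_ : SelectionState
        Full greedy trace (chosen feature, criterion value, pruned set).
    """

    def __init__(self, n_features: int | str = "auto", zero_sig_rtol: float = ZERO_SIG_RTOL):
        self.n_features = n_features
        self.zero_sig_rtol = zero_sig_rtol

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=1, dtype=float)
        d = X.shape[1]
        if self.n_features == "auto":
            m = min(default_m(d), d)
        else:
            m = int(self.n_features)
        state = select(X, m, zero_sig_rtol=self.zero_sig_rtol)
        self.selection_state_ = state
        self.selected_idx_ = list(state.selected)
        self.relevance_ = state.relevance
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        return X[:, self.selected_idx_]
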