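"""Shadow-feature (Boruta-style) all-relevant selection and its seed consensus.

Each iteration appends a column-permuted "shadow" copy of every feature,
fits a random-forest classifier, and scores a feature a "hit" when its
importance exceeds the best shadow importance. Hit counts are tested
against Binomial(iterations, 1/2), two-sided, Bonferroni-corrected across
the currently undecided features; features are confirmed or rejected as
soon as the test decides, and anything undecided at ``max_iter`` stays
tentative. The consensus wrapper repeats the run over many seeds and keeps
features confirmed in strictly more than a given fraction of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

CONFIRMED = "Confirmed"
TENTATIVE = "Tentative"
REJECTED = "Rejected"


@dataclass
class BorutaDecision:
    feature_id: str
    decision: str
    hit_count: int
    iterations_run: int
    seed: int


@dataclass
class ConsensusResult:
    confirmed_fraction: pd.Series
    selected: pd.Series
    n_repeats: int
    confirm_frac: float

    @property
    def selected_features(self) -> list[str]:
        return list(self.selected[self.selected].index)


def _check_labels(y: np.ndarray) -> None:
    values, counts = np.unique(y, return_counts=True)
    if len(values) < 2:
        raise ValueError("class labels must contain at least 2 classes")
    if counts.min() < 5:
        raise ValueError("every class needs at least 5 samples")


def boruta_run(
    X: pd.DataFrame,
    y,
    seed: int,
    max_iter: int = 50,
    n_trees: int = 50,
    alpha: float = 0.01,
    importance: str = "impurity",
) -> list[BorutaDecision]:
    """One shadow-feature selection run; returns a decision per feature."""
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    y = np.asarray(y)
    _check_labels(y)
    if importance not in ("impurity", "permutation"):
        raise ValueError("importance must be 'impurity' or 'permutation'")
    rng = np.random.default_rng(seed)
    Xv = X.values.astype(float)
    n_feat = Xv.shape[1]
    hits = np.zeros(n_feat, dtype=int)
    decided = np.array([None] * n_feat, dtype=object)
    it = 0
    for it in range(1, max_iter + 1):
        # every feature keeps its shadow throughout: the shadow pool is the
        # null distribution, and thinning it weakens the hit criterion
        shadow = np.column_stack([rng.permutation(Xv[:, j]) for j in range(n_feat)])
        data = np.hstack([Xv, shadow])
        rf = RandomForestClassifier(
            n_estimators=n_trees, n_jobs=1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(data, y)
        if importance == "impurity":
            imp = rf.feature_importances_
        else:
            imp = permutation_importance(
                rf, data, y, n_repeats=5,
                random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1,
            ).importances_mean
        shadow_max = imp[n_feat:].max()
        undecided = np.array([d is None for d in decided])
        hits[undecided] += (imp[:n_feat] > shadow_max)[undecided]
        m = int(undecided.sum())
        if m == 0:
            break
        lo = scipy.stats.binom.cdf(hits, it, 0.5)
        hi = scipy.stats.binom.sf(hits - 1, it, 0.5)
        p_two = np.minimum(2.0 * np.minimum(lo, hi), 1.0)
        sig = undecided & (p_two * m < alpha)
        for j in np.where(sig)[0]:
            decided[j] = CONFIRMED if hits[j] > it / 2 else REJECTED
        if all(d is not None for d in decided):
            break
    return [
        BorutaDecision(fid, decided[j] if decided[j] is not None else TENTATIVE,
                       int(hits[j]), it, int(seed))
        for j, fid in enumerate(X.columns)
    ]


def consensus_select(
    X: pd.DataFrame,
    y,
    seed: int,
    n_repeats: int = 100,
    confirm_frac: float = 0.9,
    **run_kwargs,
) -> ConsensusResult:
    """Repeat ``boruta_run`` over seeds seed+1..seed+n_repeats and select
    features confirmed in strictly more than ``confirm_frac`` of the runs
    (91/100 selects at the defaults; exactly 90/100 does not)."""
    counts = pd.Series(0, index=X.columns, dtype=int)
    for r in range(1, n_repeats + 1):
        decisions = boruta_run(X, y, seed=seed + r, **run_kwargs)
        for d in decisions:
            if d.decision == CONFIRMED:
                counts[d.feature_id] += 1
    return select_from_counts(counts, n_repeats, confirm_frac)


def select_from_counts(counts: pd.Series, n_repeats: int,
                       confirm_frac: float = 0.9) -> ConsensusResult:
    """Apply the strict consensus rule to per-feature confirmation counts:
    selected iff confirmed_fraction is strictly greater than confirm_frac,
    so 91/100 selects at the defaults but exactly 90/100 does not."""
    frac = counts / n_repeats
    selected = frac > confirm_frac
    return ConsensusResult(confirmed_fraction=frac, selected=selected,
                           n_repeats=n_repeats, confirm_frac=confirm_frac)
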