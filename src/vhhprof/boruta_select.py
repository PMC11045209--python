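"""Boruta all-relevant feature selection around a random forest.

Each iteration appends a shuffled ("shadow") copy of every real feature,
fits a random-forest classifier on the augmented design, and measures feature
importances.  A real feature scores a *hit* when its importance exceeds the
maximum shadow importance of that iteration; per-feature importance Z-scores
are recorded as (importance - mean shadow importance) / sd shadow importance.
After all iterations, each feature is declared

* confirmed — hit count significantly above the Bin(n, 1/2) expectation,
* rejected  — significantly below,
* tentative — neither,

using one-sided binomial tests on both sides with Holm step-down correction
at the requested alpha.  Tentative features are left tentative (no rough-fix
pass).

Importance is the mean decrease in accuracy under feature permutation
(normalized permutation importance) computed in-sample on the fitted forest;
impurity-based importance is available as a faster option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

__all__ = ["BorutaSelector", "BorutaResult", "boruta"]


@dataclass
class BorutaResult:
    """Per-feature decisions, hit counts and importance/Z-score history."""

    decisions: dict[str, str]
    hits: dict[str, int]
    n_iterations: int
    z_history: pd.DataFrame          # iterations x features
    importance_history: pd.DataFrame  # iterations x features
    shadow_stats: pd.DataFrame        # iterations x [min, mean, max] shadow Z
    alpha: float = 0.05

    @property
    def confirmed(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "confirmed"]

    @property
    def rejected(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "rejected"]

    @property
    def tentative(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "tentative"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.decisions),
                "decision": list(self.decisions.values()),
                "hits": [self.hits[f] for f in self.decisions],
                "n_iterations": self.n_iterations,
                "mean_z": [self.z_history[f].mean() for f in self.decisions],
            }
        ).set_index("feature")


def _holm(pvalues: np.ndarray, alpha: float) -> np.ndarray:
    """Holm step-down rejection mask for a family of one-sided p-values."""
    m = len(pvalues)
    order = np.argsort(pvalues)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if pvalues[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


class BorutaSelector:
    """Shadow-feature wrapper around a random-forest classifier.

    Parameters mirror the usual Boruta knobs; ``importance`` is
    ``"permutation"`` (mean decrease in accuracy) or ``"impurity"``.
    """

    def __init__(
        self,
        n_iterations: int = 100,
        forest_size: int = 500,
        alpha: float = 0.05,
        seed: int | None = None,
        importance: str = "permutation",
        n_repeats: int = 3,
        max_depth: int | None = None,
    ) -> None:
        if importance not in ("permutation", "impurity"):
            raise ValueError("importance must be 'permutation' or 'impurity'")
        self.n_iterations = n_iterations
        self.forest_size = forest_size
        self.alpha = alpha
        self.seed = 0 if seed is None else seed
        self.importance = importance
        self.n_repeats = n_repeats
        self.max_depth = max_depth

    def fit(
        self,
        table: pd.DataFrame,
        features: list[str] | None = None,
        label_col: str = "label",
    ) -> BorutaResult:
        if features is None:
            features = [
                c for c in table.columns
                if c != label_col and pd.api.types.is_numeric_dtype(table[c])
            ]
        sub = table[features + [label_col]].dropna()
        X = sub[features].to_numpy(dtype=float)
        y = sub[label_col].to_numpy(dtype=int)
        for cls in (0, 1):
            if (y == cls).sum() < 5:
                raise ValueError("need at least 5 rows per class")
        n, k = X.shape

        z_rows, imp_rows, shadow_rows = [], [], []
        hits = np.zeros(k, dtype=int)
        completed = 0
        for it in range(self.n_iterations):
            rng = np.random.default_rng(
                np.random.SeedSequence(self.seed, spawn_key=(it,))
            )
            shadow = X.copy()
            for j in range(k):
                rng.shuffle(shadow[:, j])
            X_aug = np.hstack([X, shadow])
            forest = RandomForestClassifier(
                n_estimators=self.forest_size,
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(X_aug, y)
            if self.importance == "impurity":
                imps = forest.feature_importances_
            else:
                perm = permutation_importance(
                    forest, X_aug, y,
                    n_repeats=self.n_repeats,
                    random_state=int(rng.integers(2**31 - 1)),
                    scoring="accuracy",
                    n_jobs=1,
                )
                imps = perm.importances_mean
            real, sh = imps[:k], imps[k:]
            sh_mean, sh_sd = float(sh.mean()), float(sh.std(ddof=1))
            if sh_sd == 0:
                z = np.zeros(k)
                shadow_z = np.zeros(len(sh))
            else:
                z = (real - sh_mean) / sh_sd
                shadow_z = (sh - sh_mean) / sh_sd
            hits += real > sh.max()
            z_rows.append(z)
            imp_rows.append(real)
            shadow_rows.append([shadow_z.min(), shadow_z.mean(), shadow_z.max()])
            completed += 1

        decisions = {f: "tentative" for f in features}
        if completed < 5:
            warnings.warn(
                f"only {completed} Boruta iterations completed; all features tentative"
            )
        else:
            p_hi = np.array([sps.binom.sf(h - 1, completed, 0.5) for h in hits])
            p_lo = np.array([sps.binom.cdf(h, completed, 0.5) for h in hits])
            confirm = _holm(p_hi, self.alpha)
            reject = _holm(p_lo, self.alpha)
            for j, f in enumerate(features):
                if confirm[j] and not reject[j]:
                    decisions[f] = "confirmed"
                elif reject[j] and not confirm[j]:
                    decisions[f] = "rejected"

        return BorutaResult(
            decisions=decisions,
            hits={f: int(h) for f, h in zip(features, hits)},
            n_iterations=completed,
            z_history=pd.DataFrame(z_rows, columns=features),
            importance_history=pd.DataFrame(imp_rows, columns=features),
            shadow_stats=pd.DataFrame(shadow_rows, columns=["min", "mean", "max"]),
            alpha=self.alpha,
        )


def boruta(
    table: pd.DataFrame,
    features: list[str] | None = None,
    label_col: str = "label",
    n_iterations: int = 100,
    forest_size: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
    importance: str = "permutation",
    **kwargs,
) -> BorutaResult:
    """Functional wrapper around :class:`BorutaSelector`."""
    selector = BorutaSelector(
        n_iterations=n_iterations, forest_size=forest_size, alpha=alpha,
        seed=seed, importance=importance, **kwargs,
    )
    return selector.fit(table, features, label_col)
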