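"""Binary logistic classification of VH vs VHH from physicochemical features.

The model is the standard binary logistic regression

    ln(p / (1 - p)) = b0 + b1 x1 + ... + bk xk

where p is the probability that a sequence is a VHH (label 1).  Around the
fit sit the usual repertoire-survey companions: variance-inflation-factor
(VIF) filtering of collinear predictors (VIF_j = 1 / (1 - R2_j) from
regressing predictor j on the others; drop iteratively while any exceeds the
threshold), backward stepwise elimination by likelihood-ratio test, and the
fit metrics McFadden pseudo-R2 (1 - ll / ll_null) and rank-based AUC.

Organised statsmodels-style: :class:`DomainClassLogit` is built from a
feature table and ``fit()`` returns a :class:`DomainClassLogitResults`
carrying estimates, odds ratios, confidence intervals, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.tools.sm_exceptions import PerfectSeparationError

try:  # statsmodels >= 0.13 may warn instead of raising
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
except ImportError:  # pragma: no cover
    class PerfectSeparationWarning(UserWarning):
        pass

__all__ = [
    "DomainClassLogit",
    "DomainClassLogitResults",
    "fit_logistic",
    "vif_filter",
    "VIFReport",
    "backward_eliminate",
    "mcfadden",
    "auc",
    "run_selection_pipeline",
    "SelectionReport",
]


def _design(table: pd.DataFrame, features: list[str], label_col: str):
    sub = table[features + [label_col]].dropna()
    X = sm.add_constant(sub[features].astype(float), has_constant="add")
    y = sub[label_col].astype(float)
    return X, y, len(table) - len(sub)


class DomainClassLogit:
    """Binary logistic model for VH (0) vs VHH (1) classification.

    Parameters
    ----------
    table:
        Feature table with one row per sequence, numeric feature columns and
        a binary label column.
    features:
        Predictors to include; defaults to every numeric non-label column.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        features: list[str] | None = None,
        label_col: str = "label",
    ) -> None:
        if features is None:
            features = [
                c for c in table.columns
                if c != label_col and pd.api.types.is_numeric_dtype(table[c])
            ]
        missing = [f for f in features if f not in table.columns]
        if missing:
            raise ValueError(f"features not in table: {missing}")
        labels = set(table[label_col].dropna().unique())
        if not labels <= {0, 1}:
            raise ValueError(f"label column must be binary 0/1, found {sorted(labels)}")
        if len(labels) < 2:
            raise ValueError("both classes (0 and 1) are required to fit")
        self.table = table
        self.features = list(features)
        self.label_col = label_col

    @classmethod
    def from_dataset(cls, ds, regions=("FW1", "FW2", "FW3", "FW4"),
                     include_aa_freqs: bool = False) -> "DomainClassLogit":
        from .physchem import build_feature_table

        table = build_feature_table(ds, regions=regions,
                                    include_aa_freqs=include_aa_freqs)
        return cls(table.drop(columns=["species"]))

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> "DomainClassLogitResults":
        X, y, n_dropped = _design(self.table, self.features, self.label_col)
        if n_dropped:
            warnings.warn(f"dropped {n_dropped} rows with missing feature values")
        # guard against singular designs before handing off to the optimizer
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            raise ValueError(
                "singular design matrix; collinear columns among "
                f"{list(X.columns)} (rank {rank} < {X.shape[1]})"
            )
        model = sm.Logit(y, X)
        separation = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                warnings.simplefilter("error", category=PerfectSeparationWarning)
                res = model.fit(disp=0, maxiter=maxiter, tol=tol, method="newton")
        except (PerfectSeparationError, PerfectSeparationWarning,
                RuntimeWarning, np.linalg.LinAlgError):
            separation = True
            res = model.fit(disp=0, maxiter=max(maxiter, 200), method="bfgs")
        fitted = res.predict(X)
        if not separation and (fitted[y == 1].min() > 0.999999 and
                               fitted[y == 0].max() < 0.000001):
            separation = True
        if separation:
            warnings.warn(
                "complete or quasi-complete separation detected; coefficient "
                "standard errors are inflated and unreliable"
            )
        return DomainClassLogitResults(self, res, separation, n_dropped)


@dataclass
class DomainClassLogitResults:
    """Fitted logistic model: estimates, odds ratios, metrics, summary()."""

    model: DomainClassLogit
    _res: object
    separation: bool
    n_dropped: int

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def intercept(self) -> float:
        return float(self._res.params["const"])

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    @property
    def exp_params(self) -> pd.Series:
        return np.exp(self._res.params)

    def conf_int_exp(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = np.exp(self._res.conf_int(alpha))
        ci.columns = ["lower", "upper"]
        return ci

    # -- fit metrics -------------------------------------------------------
    @property
    def llf(self) -> float:
        return float(self._res.llf)

    @property
    def llnull(self) -> float:
        return float(self._res.llnull)

    @property
    def aic(self) -> float:
        return float(self._res.aic)

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    @property
    def mcfadden(self) -> float:
        return mcfadden(self)

    @property
    def fittedvalues(self) -> pd.Series:
        X, y, _ = _design(self.model.table, self.model.features, self.model.label_col)
        return self._res.predict(X)

    @property
    def auc(self) -> float:
        X, y, _ = _design(self.model.table, self.model.features, self.model.label_col)
        return auc(self._res.predict(X), y)

    @property
    def variable_importance(self) -> pd.Series:
        """Absolute Wald z-statistic per term (intercept excluded)."""
        z = (self.params / self.bse).drop("const").abs()
        z.name = "variable_importance"
        return z

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        """Survey-style coefficient table: Beta, Exp(Beta), p, CI, importance."""
        ci = self.conf_int_exp(alpha)
        frame = pd.DataFrame(
            {
                "Beta": self.params,
                "Exp(Beta)": self.exp_params,
                "p-value": self.pvalues,
                "CI lower": ci["lower"],
                "CI upper": ci["upper"],
            }
        )
        vi = self.variable_importance
        frame["Variable importance"] = vi.reindex(frame.index)
        frame["VHH-enriched"] = (frame["Exp(Beta)"] > 1).astype(object)
        frame.loc["const", "VHH-enriched"] = pd.NA
        order = ["const"] + [f for f in frame.index if f != "const"]
        return frame.loc[order]


def fit_logistic(
    table: pd.DataFrame, features: list[str], label_col: str = "label"
) -> DomainClassLogitResults:
    """Convenience wrapper: build and fit in one call."""
    return DomainClassLogit(table, features, label_col).fit()


# ---------------------------------------------------------------------------
# metrics


def mcfadden(fit: DomainClassLogitResults) -> float:
    """McFadden pseudo-R2 = 1 - ll / ll_null."""
    if fit.llnull == 0:
        raise ValueError("degenerate null log-likelihood of zero")
    return 1.0 - fit.llf / fit.llnull


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties contribute one half."""
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both labels present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# VIF filtering


@dataclass
class VIFReport:
    """Retained features with final VIFs, plus the removal trail."""

    vif: pd.Series
    removed: list[tuple[str, float]] = field(default_factory=list)
    threshold: float = 10.0

    @property
    def retained(self) -> list[str]:
        return list(self.vif.index)


def _vif_values(X: np.ndarray, names: list[str]) -> pd.Series:
    """VIF_j = 1 / (1 - R2_j), regressing column j on the others + intercept."""
    n, k = X.shape
    out = {}
    ones = np.ones((n, 1))
    for j, name in enumerate(names):
        yj = X[:, j]
        if np.allclose(yj, yj[0]):
            out[name] = np.inf  # constant column
            continue
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_filter(
    table: pd.DataFrame,
    features: list[str],
    threshold: float = 10.0,
    label_col: str = "label",
) -> VIFReport:
    """Iteratively drop the highest-VIF predictor above the threshold.

    Recomputes VIFs after each removal; ties at the maximum break toward the
    lexicographically later column name.  Constant columns carry infinite VIF
    and go first.
    """
    if len(features) < 2:
        raise ValueError("VIF filtering needs at least two features")
    sub = table[features].dropna().astype(float)
    current = list(features)
    removed: list[tuple[str, float]] = []
    while len(current) >= 2:
        vifs = _vif_values(sub[current].to_numpy(), current)
        worst = vifs.max()
        if not (worst > threshold):
            break
        ties = [name for name in current if vifs[name] == worst]
        victim = sorted(ties)[-1]
        removed.append((victim, float(worst)))
        current.remove(victim)
    final = _vif_values(sub[current].to_numpy(), current) if len(current) >= 2 else (
        pd.Series({current[0]: 1.0}) if current else pd.Series(dtype=float)
    )
    return VIFReport(vif=final, removed=removed, threshold=threshold)


# ---------------------------------------------------------------------------
# backward stepwise elimination by likelihood-ratio test


def backward_eliminate(
    table: pd.DataFrame,
    features: list[str],
    alpha: float = 0.05,
    label_col: str = "label",
) -> DomainClassLogitResults:
    """Backward stepwise elimination with the likelihood-ratio test.

    At each step the feature whose removal gives the largest LRT p-value is
    dropped if that p-value exceeds ``alpha``
    (LRT statistic 2*(ll_full - ll_reduced) ~ chi-square, df 1); stops when
    every remaining removal is significant.  The returned results object
    carries the elimination trail in ``eliminated``.
    """
    current = list(features)
    trail: list[tuple[str, float]] = []
    fit = fit_logistic(table, current, label_col)
    while len(current) > 1:
        worst_p, worst_feature, worst_fit = -1.0, None, None
        for feature in current:
            reduced = [f for f in current if f != feature]
            red_fit = fit_logistic(table, reduced, label_col)
            lrt = 2.0 * (fit.llf - red_fit.llf)
            p = float(sps.chi2.sf(max(lrt, 0.0), df=1))
            if p > worst_p:
                worst_p, worst_feature, worst_fit = p, feature, red_fit
        if worst_p <= alpha:
            break
        trail.append((worst_feature, worst_p))
        current.remove(worst_feature)
        fit = worst_fit
    fit.eliminated = trail
    return fit


# ---------------------------------------------------------------------------
# end-to-end selection pipeline


@dataclass
class SelectionReport:
    """Per-model reports from the VIF -> stepwise -> metrics pipeline."""

    mode: str
    models: dict[str, DomainClassLogitResults]
    vif_reports: dict[str, VIFReport]

    def summaries(self) -> dict[str, pd.DataFrame]:
        out = {}
        for name, fit in self.models.items():
            frame = fit.summary()
            vif = self.vif_reports[name].vif
            frame["VIF"] = vif.reindex(frame.index)
            frame.attrs["McFadden R2"] = fit.mcfadden
            frame.attrs["AUC"] = fit.auc
            frame.attrs["AIC"] = fit.aic
            out[name] = frame
        return out


def run_selection_pipeline(
    table: pd.DataFrame,
    mode: str = "collective",
    vif_threshold: float = 10.0,
    alpha: float = 0.05,
    label_col: str = "label",
) -> SelectionReport:
    """VIF filtering, then backward stepwise elimination, then metrics.

    ``collective`` fits one model over all framework features;
    ``per_region`` fits one model per framework region (feature names are
    expected to carry the ``<region>_<Class>`` convention).
    """
    if mode not in ("collective", "per_region"):
        raise ValueError("mode must be 'collective' or 'per_region'")
    feature_names = [
        c for c in table.columns
        if c != label_col and pd.api.types.is_numeric_dtype(table[c])
    ]
    if mode == "collective":
        groups = {"collective": feature_names}
    else:
        groups = {}
        for name in feature_names:
            region = name.split("_", 1)[0]
            groups.setdefault(region, []).append(name)

    models, vif_reports = {}, {}
    for group, feats in groups.items():
        report = vif_filter(table, feats, threshold=vif_threshold, label_col=label_col)
        fit = backward_eliminate(table, report.retained, alpha=alpha, label_col=label_col)
        models[group] = fit
        vif_reports[group] = report
    return SelectionReport(mode=mode, models=models, vif_reports=vif_reports)
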