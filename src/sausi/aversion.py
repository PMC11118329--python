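"""Composite social-aversion index and housing-condition decoding.

The composite index converts each behavioral metric to a z-score over a
reference population (the pooled cohort by default), aligns signs so that
larger always means *more aversive* (motivation-direction metrics such as
prosocial initiations and social-chamber preference are negated), and
averages across behaviors.  Behaviors are grouped into three categories —
social fear, social hesitancy, and social motivation — and per-category
sub-means are reported alongside the composite.

Decoding is multivariable binary logistic regression on internally
standardized features with an L2 (ridge) penalty, fit by convex optimization
from a zero start; the report carries the standardized coefficients (ranked
by magnitude as feature importances) and the training accuracy, i.e. the
fraction of subjects correctly labelled on the fitting data itself.

Both steps are exposed as scikit-learn style estimators
(:class:`AversionIndex`, :class:`HousingDecoder`) with thin functional
wrappers (:func:`zscore_table`, :func:`composite_aversion`,
:func:`fit_logistic_decoder`, :func:`group_ttest`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

SOCIAL_FEAR = "social_fear"
SOCIAL_HESITANCY = "social_hesitancy"
SOCIAL_MOTIVATION = "social_motivation"


@dataclass(frozen=True)
class CategoryMap:
    """Maps each behavior entering the composite to its category and its
    aversion sign (+1 higher-is-more-aversive, -1 higher-is-less-aversive)."""

    category: dict[str, str]
    sign: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.category) != set(self.sign):
            raise ValueError("category and sign must cover the same behaviors")
        if not all(s in (-1, +1) for s in self.sign.values()):
            raise ValueError("signs must be +1 or -1")

    @property
    def behaviors(self) -> list[str]:
        return list(self.category)


#: behaviors combined into the default social-aversion index
DEFAULT_CATEGORY_MAP = CategoryMap(
    category={
        "social_freeze_s": SOCIAL_FEAR,
        "social_reactivity_pct": SOCIAL_FEAR,
        "first_tunnel_shelter_s": SOCIAL_HESITANCY,
        "reverse_count": SOCIAL_HESITANCY,
        "reverse_s": SOCIAL_HESITANCY,
        "latency_to_social_s": SOCIAL_HESITANCY,
        "prosocial_initiations": SOCIAL_MOTIVATION,
        "chamber_preference_pct": SOCIAL_MOTIVATION,
    },
    sign={
        "social_freeze_s": +1,
        "social_reactivity_pct": +1,
        "first_tunnel_shelter_s": +1,
        "reverse_count": +1,
        "reverse_s": +1,
        "latency_to_social_s": +1,
        "prosocial_initiations": -1,
        "chamber_preference_pct": -1,
    },
)


class DegenerateFeatureError(ValueError):
    """A feature has zero spread in the reference population."""


class ConvergenceError(RuntimeError):
    """The decoder optimizer stopped before reaching the stated tolerance."""


# ---------------------------------------------------------------------------
# z-scores and the composite
# ---------------------------------------------------------------------------


class AversionIndex(TransformerMixin, BaseEstimator):
    """Z-score behaviors against a reference population and average the
    sign-aligned scores into a composite aversion index.

    Parameters
    ----------
    category_map
        Behavior -> (category, sign) mapping; defaults to the standard
        fear / hesitancy / motivation set.
    ddof
        Delta degrees of freedom for the reference sd (1 = sample sd).

    The reference population is whatever table is passed to :meth:`fit`
    (pooled cohort by default usage; pass a single-condition subset for a
    control-referenced index).  Flagged-missing entries (NaN) are skipped:
    they do not enter the reference statistics and a subject's composite
    averages only its defined behaviors.

    ``on_degenerate`` controls zero-spread behaviors in the reference
    population: ``'raise'`` (default) errors naming the behavior;
    ``'drop'`` removes it from the index (a constant carries no group
    information) and records it in ``dropped_``.
    """

    def __init__(
        self,
        category_map: CategoryMap | None = None,
        ddof: int = 1,
        on_degenerate: str = "raise",
    ):
        self.category_map = category_map
        self.ddof = ddof
        self.on_degenerate = on_degenerate

    def _map(self) -> CategoryMap:
        return self.category_map if self.category_map is not None else DEFAULT_CATEGORY_MAP

    def fit(self, X: pd.DataFrame, y=None) -> "AversionIndex":
        cmap = self._map()
        missing = [b for b in cmap.behaviors if b not in X.columns]
        if missing:
            raise KeyError(f"score table lacks behaviors {missing}")
        cols = X[cmap.behaviors].astype(float)
        counts = cols.notna().sum()
        if (counts < 2).any():
            bad = list(counts.index[counts < 2])
            raise ValueError(f"need >=2 defined values per behavior; too few in {bad}")
        self.mean_ = cols.mean(skipna=True)
        self.sd_ = cols.std(ddof=self.ddof, skipna=True)
        bad = list(self.sd_.index[(self.sd_ == 0) | self.sd_.isna()])
        if bad and self.on_degenerate != "drop":
            raise DegenerateFeatureError(
                f"zero spread in reference population for {bad}"
            )
        self.dropped_ = bad
        self.behaviors_ = [b for b in cmap.behaviors if b not in bad]
        if not self.behaviors_:
            raise DegenerateFeatureError("every behavior is degenerate")
        self.mean_ = self.mean_[self.behaviors_]
        self.sd_ = self.sd_[self.behaviors_]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-behavior z-scores; flagged-missing values stay missing."""
        check_is_fitted(self, "mean_")
        cols = X[self.behaviors_].astype(float)
        return (cols - self.mean_) / self.sd_

    def composite(self, X: pd.DataFrame) -> pd.DataFrame:
        """Composite aversion score and per-category sub-means per subject.

        Returns a frame with columns ``composite``, ``social_fear``,
        ``social_hesitancy``, ``social_motivation``.  A subject with every
        behavior flagged missing gets a flagged (NaN) composite.
        """
        z = self.transform(X)
        cmap = self._map()
        signs = pd.Series(cmap.sign, dtype=float)[self.behaviors_]
        aligned = z * signs
        out = pd.DataFrame(index=X.index)
        out["composite"] = aligned.mean(axis=1, skipna=True)
        for cat in (SOCIAL_FEAR, SOCIAL_HESITANCY, SOCIAL_MOTIVATION):
            members = [b for b in self.behaviors_ if cmap.category[b] == cat]
            if members:
                out[cat] = aligned[members].mean(axis=1, skipna=True)
        return out


def zscore_table(
    scores: pd.DataFrame,
    behaviors: list[str],
    reference: pd.DataFrame | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Z-score the given columns against *reference* (default: *scores*
    itself, i.e. pooled-cohort statistics)."""
    cmap = CategoryMap(
        category={b: SOCIAL_FEAR for b in behaviors},
        sign={b: +1 for b in behaviors},
    )
    idx = AversionIndex(category_map=cmap, ddof=ddof)
    idx.fit(scores if reference is None else reference)
    return idx.transform(scores)


def composite_aversion(
    scores: pd.DataFrame,
    category_map: CategoryMap | None = None,
    reference: pd.DataFrame | None = None,
    ddof: int = 1,
    on_degenerate: str = "raise",
) -> pd.DataFrame:
    """Fit-and-score convenience wrapper around :class:`AversionIndex`."""
    idx = AversionIndex(
        category_map=category_map, ddof=ddof, on_degenerate=on_degenerate
    )
    idx.fit(scores if reference is None else reference)
    return idx.composite(scores)


# ---------------------------------------------------------------------------
# logistic decoding
# ---------------------------------------------------------------------------


@dataclass
class DecoderReport:
    """Fit summary of the housing-condition decoder."""

    feature_names: list[str]
    coef: np.ndarray  # standardized-feature coefficients
    intercept: float
    classes: list
    training_accuracy: float
    l2_strength: float
    n_subjects: int

    def ranked_features(self) -> pd.Series:
        """Coefficients sorted by decreasing magnitude (feature importance)."""
        s = pd.Series(self.coef, index=self.feature_names)
        return s.reindex(s.abs().sort_values(ascending=False).index)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "coef": [float(c) for c in self.coef],
            "intercept": float(self.intercept),
            "classes": [str(c) for c in self.classes],
            "training_accuracy": float(self.training_accuracy),
            "l2_strength": float(self.l2_strength),
            "n_subjects": int(self.n_subjects),
        }


class HousingDecoder(ClassifierMixin, BaseEstimator):
    """Binary logistic decoder of group membership from behavioral features.

    Features are standardized internally (mean 0, sd 1 over the fitting
    data) so coefficient magnitudes are comparable as importances.  The fit
    minimizes the L2-penalized negative log-likelihood

        sum_i log(1 + exp(-s_i (x_i . w + b))) + l2_strength * ||w||^2 / 2

    (s_i = +/-1, intercept unpenalized), a strictly convex problem solved by
    L-BFGS from a zero start, hence deterministic.  The default penalty is
    deliberately weak relative to the cohort sizes this is used at.
    """

    def __init__(
        self,
        l2_strength: float = 1.0,
        max_iter: int = 10_000,
        tol: float = 1e-10,
    ):
        self.l2_strength = l2_strength
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y) -> "HousingDecoder":
        X = pd.DataFrame(X)
        self.feature_names_ = [str(c) for c in X.columns]
        Xv = X.to_numpy(dtype=float)
        if not np.all(np.isfinite(Xv)):
            raise ValueError("decoder features must be finite (impute or drop first)")
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        if counts.min() < 2:
            raise ValueError("need >=2 subjects per class")
        if self.l2_strength <= 0:
            raise ValueError("l2_strength must be positive")
        self.classes_ = classes
        self.feature_mean_ = Xv.mean(axis=0)
        sd = Xv.std(axis=0)
        self.feature_sd_ = np.where(sd > 0, sd, 1.0)
        Z = (Xv - self.feature_mean_) / self.feature_sd_
        clf = LogisticRegression(
            C=1.0 / self.l2_strength,
            solver="lbfgs",
            tol=self.tol,
            max_iter=self.max_iter,
        )
        clf.fit(Z, y)
        self.coef_ = clf.coef_[0].copy()
        self.intercept_ = float(clf.intercept_[0])
        g = self._gradient_norm(Z, y)
        if not clf.n_iter_[0] < self.max_iter:
            raise ConvergenceError(
                f"decoder did not converge in {self.max_iter} iterations "
                f"(gradient norm {g:.3e})"
            )
        self.gradient_norm_ = g
        self.training_accuracy_ = float(np.mean(clf.predict(Z) == y))
        self._n_fit = len(y)
        self._clf = clf
        return self

    def _standardize(self, X) -> np.ndarray:
        Xv = pd.DataFrame(X).to_numpy(dtype=float)
        return (Xv - self.feature_mean_) / self.feature_sd_

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return self._clf.predict(self._standardize(X))

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        return self._clf.predict_proba(self._standardize(X))

    def penalized_negloglik(
        self, Z: np.ndarray, y, coef: np.ndarray | None = None,
        intercept: float | None = None,
    ) -> float:
        """The fitted objective, evaluated at (coef, intercept) on
        standardized features — the quantity the optimizer minimizes."""
        w = self.coef_ if coef is None else np.asarray(coef, dtype=float)
        b = self.intercept_ if intercept is None else float(intercept)
        s = np.where(np.asarray(y) == self.classes_[1], 1.0, -1.0)
        margins = s * (Z @ w + b)
        return float(
            np.sum(np.logaddexp(0.0, -margins)) + 0.5 * self.l2_strength * w @ w
        )

    def _gradient_norm(self, Z: np.ndarray, y) -> float:
        s01 = (np.asarray(y) == self.classes_[1]).astype(float)
        p = 1.0 / (1.0 + np.exp(-(Z @ self.coef_ + self.intercept_)))
        gw = Z.T @ (p - s01) + self.l2_strength * self.coef_
        gb = np.sum(p - s01)
        return float(np.sqrt(gw @ gw + gb * gb))

    def report(self) -> DecoderReport:
        check_is_fitted(self, "coef_")
        return DecoderReport(
            feature_names=self.feature_names_,
            coef=self.coef_.copy(),
            intercept=self.intercept_,
            classes=list(self.classes_),
            training_accuracy=self.training_accuracy_,
            l2_strength=self.l2_strength,
            n_subjects=self._n_fit,
        )


def fit_logistic_decoder(
    features: pd.DataFrame,
    labels,
    l2_strength: float = 1.0,
    max_iter: int = 10_000,
    tol: float = 1e-10,
) -> DecoderReport:
    """Fit :class:`HousingDecoder` and return its :class:`DecoderReport`."""
    dec = HousingDecoder(l2_strength=l2_strength, max_iter=max_iter, tol=tol)
    dec.fit(features, labels)
    return dec.report()


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    degenerate: bool = False


def group_ttest(values, labels, equal_var: bool = True) -> TTestResult:
    """Two-tailed independent-samples t-test between the two label groups.

    Student's pooled-variance test by default (``equal_var=False`` for
    Welch).  NaN values are dropped per group.  If the pooled sd is zero the
    result is flagged degenerate: t=0, p=1 for identical groups, otherwise
    t=NaN, p=0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(classes)}")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 defined values per group")
    df = len(a) + len(b) - 2 if equal_var else np.nan
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, df, degenerate=True)
        return TTestResult(float("nan"), 0.0, df, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df_out = df if equal_var else float(res.df)
    return TTestResult(float(res.statistic), float(res.pvalue), df_out)
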