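"""scikit-learn-style estimators over the library functions.

X follows the sklearn orientation (n_samples x n_genes); y is the vector of
group labels in {1, 2}. ``CountFilter`` is a feature selector (SelectorMixin)
whose mask is a Table-2 keep-mask; ``VoomTester`` exposes the moderated-t
p-values; ``AdaptiveFilterDE`` runs the full adaptive procedure.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .containers import CountMatrix, FilterSpec, table2_battery
from .de import tmm_factors, voom_transform, moderated_test
from .filters import apply_filter
from .adaptive import run_battery, select, adaptive_analyze
from .containers import ScenarioConfig

__all__ = ["CountFilter", "VoomTester", "AdaptiveFilterDE"]


def _to_count_matrix(X, y) -> CountMatrix:
    X, y = check_X_y(X, y, dtype="numeric", ensure_min_samples=2)
    return CountMatrix.from_xy(X, y)


class CountFilter(SelectorMixin, BaseEstimator):
    """Gene filter as a sklearn feature selector.

    Parameters
    ----------
    family : one of none, basic, mean, max, cpm, jaccard, zero
    threshold : family-specific parameter (see FilterSpec)
    """

    def __init__(self, family: str = "basic", threshold=None):
        self.family = family
        self.threshold = threshold

    def fit(self, X, y=None):
        X = check_array(X, dtype="numeric")
        spec = FilterSpec(self.family, self.threshold)
        if self.family == "jaccard":
            if y is None:
                raise ValueError("the jaccard filter needs group labels y")
            cm = _to_count_matrix(X, y)
            res = apply_filter(spec, cm, groups=cm.groups)
        else:
            n = X.shape[0]
            n1 = n // 2
            y_eff = np.r_[np.ones(n1), np.full(n - n1, 2)] if y is None else y
            cm = CountMatrix.from_xy(X, y_eff)
            res = apply_filter(spec, cm, groups=cm.groups,
                               n1=cm.n1, n2=cm.n2)
        self.filter_result_ = res
        self.keep_mask_ = res.keep
        self.proportion_filtered_ = res.proportion_filtered
        self.realized_threshold_ = res.realized_threshold
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "keep_mask_")
        return self.keep_mask_


class VoomTester(BaseEstimator):
    """TMM + voom transform + moderated weighted t-test, as an estimator.

    Fitted attributes: ``p_values_``, ``t_statistics_``, ``tmm_factors_``,
    ``weights_``, ``prior_df_``, ``prior_var_``.
    """

    def __init__(self, prior_df=None, span: float = 0.5):
        self.prior_df = prior_df
        self.span = span

    def fit(self, X, y):
        cm = _to_count_matrix(X, y)
        factors = tmm_factors(cm)
        norm = voom_transform(cm, factors=factors, groups=cm.groups,
                              span=self.span)
        result = moderated_test(norm, cm.groups, prior_df=self.prior_df)
        self.tmm_factors_ = factors
        self.log_cpm_ = norm.log_cpm
        self.weights_ = norm.weights
        self.p_values_ = result.p_values
        self.t_statistics_ = result.test_statistics
        self.df_ = result.df
        self.prior_df_ = result.prior_df
        self.prior_var_ = result.prior_var
        self.n_features_in_ = X.shape[1]
        return self


class AdaptiveFilterDE(BaseEstimator):
    """The adaptive filtering procedure as a fit-style estimator.

    fit(X, y) runs the filter battery, adjusts per filter, and applies the
    max-rejections selection rule with the reference fallback. Fitted
    attributes: ``R_`` (per-filter rejection counts), ``k_`` (chosen index),
    ``chosen_``, ``fallback_fired_``, ``rejected_`` (gene-level mask),
    ``battery_``.
    """

    def __init__(self, battery=None, alpha: float = 0.05,
                 adjustment: str = "lfdr", order: str = "a", l: int = 5,
                 reference: FilterSpec | str = "jaccard",
                 strict_fallback: bool = False):
        self.battery = battery
        self.alpha = alpha
        self.adjustment = adjustment
        self.order = order
        self.l = l
        self.reference = reference
        self.strict_fallback = strict_fallback

    def fit(self, X, y):
        cm = _to_count_matrix(X, y)
        reference = (self.reference if isinstance(self.reference, FilterSpec)
                     else FilterSpec(self.reference))
        battery = (tuple(self.battery) if self.battery is not None
                   else tuple(table2_battery(cm.n1, cm.n2)))
        config = ScenarioConfig(m=cm.m, n1=cm.n1, n2=cm.n2, alpha=self.alpha,
                                adjustment=self.adjustment, order=self.order,
                                filter_battery=battery, l=self.l,
                                reference=reference, n_reps=1)
        result = run_battery(cm, config.filter_battery, alpha=self.alpha,
                             adjustment=self.adjustment, order=self.order)
        selection = adaptive_analyze(cm, config, battery_result=result,
                                     strict=self.strict_fallback)
        self.battery_ = config.filter_battery
        self.battery_result_ = result
        self.R_ = selection.R
        self.k_ = selection.k
        self.chosen_ = selection.chosen
        self.fallback_fired_ = selection.fallback_fired
        self.rejected_ = selection.rejected_genes
        self.n_rejected_ = selection.n_rejected
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X=None):
        """Gene-level rejection mask of the chosen filter's analysis."""
        check_is_fitted(self, "rejected_")
        return self.rejected_
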