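"""scikit-learn style estimators wrapping the asymmetry pipeline.

``LSADExtractor`` is transform-shaped: it turns per-subject frame
sequences into the 30 asymmetry measures (29 per-pair LSADs + their sum),
usable as a feature extractor in an sklearn pipeline.  ``DepthCoefficientTuner``
is fit-shaped: given a labelled cohort it selects the depth coefficient by
significance-count maximization and then transforms subjects at the chosen
value.  Both follow the sklearn contract (get_params/set_params, fitted
attributes with a trailing underscore) so clone/GridSearchCV compose with
them; X is a list of FrameSequence objects (or (FrameSequence, DepthImage)
tuples), not a numeric matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import DEFAULT_DEPTH_COEFFICIENT
from .pairs import default_pair_table
from .stats import measure_columns
from .tuning import cohort_measures, tune_depth_coefficient

__all__ = ["LSADExtractor", "DepthCoefficientTuner"]


class LSADExtractor(TransformerMixin, BaseEstimator):
    """Extract per-subject LSAD profiles as a feature matrix.

    Parameters
    ----------
    c : float, default 0.016
        Depth coefficient weighting mm into the normalized frame.
    pair_table : PairTable or None
        Bilateral pairing; None selects the standard 68-point scheme.
    allow_scaling : bool, default False
        Similarity-mode Procrustes (sensitivity analysis); the standard
        measure is rigid.
    seed : int, default 0
        Seed for the foreground clustering used in depth repair.
    """

    def __init__(
        self,
        c: float = DEFAULT_DEPTH_COEFFICIENT,
        pair_table=None,
        allow_scaling: bool = False,
        seed: int = 0,
    ):
        self.c = c
        self.pair_table = pair_table
        self.allow_scaling = allow_scaling
        self.seed = seed

    def _pairs(self):
        return self.pair_table if self.pair_table is not None else default_pair_table()

    def fit(self, X, y=None):
        """Stateless; records feature names and returns self."""
        self.feature_names_out_ = np.asarray(measure_columns(self._pairs()), dtype=object)
        self.n_features_out_ = self.feature_names_out_.size
        return self

    def transform(self, X) -> np.ndarray:
        """(n_subjects, 30) array of asymmetry measures."""
        if not hasattr(self, "feature_names_out_"):
            self.fit(X)
        return cohort_measures(list(X), float(self.c), self._pairs(), seed=self.seed)

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "feature_names_out_"):
            self.fit(None)
        return self.feature_names_out_


class DepthCoefficientTuner(TransformerMixin, BaseEstimator):
    """Select the depth coefficient from a labelled cohort.

    ``fit(X, y)`` screens ``grid`` (default 0.000..0.050 step 0.001): at
    each candidate the 30 measures are recomputed for all subjects and a
    one-tailed (case > control) independent t-test counts significant
    measures; the maximizing value wins, ties to the smallest c.

    Attributes
    ----------
    chosen_c_ : float
    grid_ : ndarray
    significant_counts_ : ndarray of int
    pvalues_ : ndarray, (len(grid), 30) one-tailed p-values
    """

    def __init__(
        self,
        grid=None,
        alpha: float = 0.05,
        case_label: str = "case",
        variant: str = "pooled",
        pair_table=None,
        seed: int = 0,
    ):
        self.grid = grid
        self.alpha = alpha
        self.case_label = case_label
        self.variant = variant
        self.pair_table = pair_table
        self.seed = seed

    def fit(self, X, y):
        pairs = self.pair_table if self.pair_table is not None else default_pair_table()
        result = tune_depth_coefficient(
            list(X),
            list(y),
            grid=self.grid,
            alpha=self.alpha,
            case_label=self.case_label,
            variant=self.variant,
            pairs=pairs,
            seed=self.seed,
        )
        self.chosen_c_ = result.chosen_c
        self.grid_ = result.grid
        self.significant_counts_ = result.significant_counts
        self.pvalues_ = result.per_c_pvalues
        self.result_ = result
        return self

    def transform(self, X) -> np.ndarray:
        """Measures at the tuned depth coefficient."""
        if not hasattr(self, "chosen_c_"):
            raise RuntimeError("DepthCoefficientTuner must be fitted before transform")
        pairs = self.pair_table if self.pair_table is not None else default_pair_table()
        return cohort_measures(list(X), self.chosen_c_, pairs, seed=self.seed)
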