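"""Shared machinery for the genomic-prediction estimators.

All estimators follow the scikit-learn protocol: ``fit(X, y)`` takes raw
allele dosages (``n x m``, values 0/1/2) for the reference population,
``predict(X)`` returns phenotype-scale predictions for selection candidates,
and ``gebv(X)`` returns genomic estimated breeding values (the marker term
``Z g`` alone, without the population mean).

Standardization is always anchored to the training data: allele frequencies
estimated on the reference set are reused to centre and scale candidate
genotypes, so that GEBV are on the training scale.  Markers that are
monomorphic in the reference set carry a zero effect for prediction.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .genotypes import GenotypeMatrix, compute_allele_frequencies, standardize


class GenomicPredictionMixin(RegressorMixin, BaseEstimator):
    """Dosage-in, breeding-value-out plumbing shared by all models."""

    def _standardize_train(self, X, y):
        if isinstance(X, GenotypeMatrix):
            g = X
        else:
            X = np.asarray(X)
            g = GenotypeMatrix(
                [f"s{i}" for i in range(X.shape[0])],
                [f"m{j}" for j in range(X.shape[1])],
                X,
            )
        y = np.asarray(y, dtype=float).ravel()
        if y.size != g.n:
            raise ValueError(f"{y.size} phenotypes for {g.n} individuals")
        freqs = compute_allele_frequencies(g)
        sg = standardize(g, freqs)
        self.n_features_in_ = g.m
        self.freqs_ = freqs
        self.kept_markers_ = sg.kept_markers
        return sg, y

    def _standardize_new(self, X):
        check_is_fitted(self, "coef_")
        if isinstance(X, GenotypeMatrix):
            X = X.dosages
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} markers; fitted on {self.n_features_in_}"
            )
        kept = self.kept_markers_
        p = self.freqs_[kept]
        d = X[:, kept].astype(float)
        miss = d < 0
        if miss.any():
            d[miss] = (2.0 * p)[np.nonzero(miss)[1]]
        return (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))

    def gebv(self, X) -> np.ndarray:
        """Genomic estimated breeding values ``Z g`` (no intercept)."""
        return self._standardize_new(X) @ self.coef_[self.kept_markers_]

    def predict(self, X) -> np.ndarray:
        """Phenotype-scale prediction: fitted mean plus GEBV."""
        return self.mu_ + self.gebv(X)
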