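"""Cohort z-score standardization and signed signature scores.

The score of sample *i* for a signature with an up-set U and a down-set D is

    score_i = sum_{g in U} z_{g,i} - sum_{g in D} z_{g,i}

where z_{g,i} = (x_{g,i} - mu_g) / sigma_g, with mu_g and sigma_g the mean and
(n-1 denominator) standard deviation of gene g across the whole cohort. Genes
absent from the matrix are dropped (coverage is recorded); genes with zero
cohort variance contribute nothing.

The transformation is exposed both as scikit-learn estimators
(:class:`CohortZScorer`, :class:`SignatureScorer`, samples as rows) and as
thin functions over genes x samples frames (:func:`compute_zscores`,
:func:`score_signature`, :func:`score_all`).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import ScoreTable, SignatureDefinition, ZScoreResult

logger = logging.getLogger(__name__)

__all__ = [
    "CohortZScorer",
    "SignatureScorer",
    "compute_zscores",
    "score_signature",
    "score_all",
    "rank_and_segregate",
    "dichotomize_gene",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class CohortZScorer(TransformerMixin, BaseEstimator):
    """Per-gene cohort standardization (samples as rows, genes as columns).

    Parameters
    ----------
    log_transform : bool, default True
        Apply log2(x + 1) before standardization; appropriate for
        abundance-scale (RPKM/TPM-like) input, switch off for data already on
        a log scale.
    ddof : int, default 1
        Delta degrees of freedom of the standard deviation (1 = sample SD).
    allow_out_of_cohort : bool, default False
        Whether :meth:`transform` may be applied to samples other than the
        cohort seen at fit time. Scoring a held-out subset against cohort-wide
        mu/sigma changes the meaning of the score, so it must be opted into.

    Attributes
    ----------
    mu_ : ndarray of shape (n_genes,)
        Cohort mean per gene (after the optional log transform).
    sigma_ : ndarray of shape (n_genes,)
        Cohort standard deviation per gene.
    degenerate_ : ndarray of bool
        True for genes with sigma == 0; their z values are set to 0.
    """

    def __init__(
        self,
        log_transform: bool = True,
        ddof: int = 1,
        allow_out_of_cohort: bool = False,
    ):
        self.log_transform = log_transform
        self.ddof = ddof
        self.allow_out_of_cohort = allow_out_of_cohort

    def fit(self, X, y=None):
        X = _as_frame(X)
        if X.shape[0] < 2:
            raise ValueError(
                f"cohort standardization needs >= 2 samples, got {X.shape[0]}"
            )
        values = X.to_numpy(dtype=float)
        if self.log_transform:
            if (values < 0).any():
                raise ValueError("log2(x+1) transform requires non-negative input")
            values = np.log2(values + 1.0)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        self.sample_ids_ = np.asarray(X.index)
        self.mu_ = values.mean(axis=0)
        # an exactly constant gene must get sigma 0 even when floating-point
        # summation leaves a ~1e-16 residual in the computed SD
        self.degenerate_ = np.ptp(values, axis=0) == 0.0
        self.sigma_ = np.where(
            self.degenerate_, 0.0, values.std(axis=0, ddof=self.ddof)
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "mu_")
        X = _as_frame(X)
        if X.shape[1] != self.n_features_in_ or not np.array_equal(
            np.asarray(X.columns), self.feature_names_in_
        ):
            raise ValueError("transform input genes differ from the fitted cohort")
        in_cohort = np.isin(np.asarray(X.index), self.sample_ids_)
        if not in_cohort.all() and not self.allow_out_of_cohort:
            raise ValueError(
                "samples outside the fitted cohort; z-scores would use "
                "cohort-wide mu/sigma from a different cohort — set "
                "allow_out_of_cohort=True to permit this explicitly"
            )
        values = X.to_numpy(dtype=float)
        if self.log_transform:
            values = np.log2(values + 1.0)
        sigma = np.where(self.degenerate_, 1.0, self.sigma_)
        z = (values - self.mu_) / sigma
        z[:, self.degenerate_] = 0.0
        return pd.DataFrame(z, index=X.index, columns=X.columns)


class SignatureScorer(TransformerMixin, BaseEstimator):
    """Signed signature scoring on top of cohort standardization.

    ``fit`` learns cohort mu/sigma; ``transform`` returns a samples x
    signatures score frame. Typical use is ``fit_transform`` on the whole
    cohort (the score is a within-cohort contrast).

    Parameters
    ----------
    signatures : sequence of SignatureDefinition
    log_transform, ddof, allow_out_of_cohort
        Passed to the underlying :class:`CohortZScorer`.
    min_coverage_warn : float, default 0.5
        Signatures with a smaller fraction of their genes present in the
        matrix are logged as poorly covered.

    Attributes
    ----------
    coverage_ : Series indexed by signature name
        Fraction of each signature's genes found among the fitted genes.
    zscorer_ : CohortZScorer
        The fitted standardizer.
    """

    def __init__(
        self,
        signatures: Sequence[SignatureDefinition] = (),
        log_transform: bool = True,
        ddof: int = 1,
        allow_out_of_cohort: bool = False,
        min_coverage_warn: float = 0.5,
    ):
        self.signatures = signatures
        self.log_transform = log_transform
        self.ddof = ddof
        self.allow_out_of_cohort = allow_out_of_cohort
        self.min_coverage_warn = min_coverage_warn

    def fit(self, X, y=None):
        if len(self.signatures) == 0:
            raise ValueError("at least one signature is required")
        X = _as_frame(X)
        self.zscorer_ = CohortZScorer(
            log_transform=self.log_transform,
            ddof=self.ddof,
            allow_out_of_cohort=self.allow_out_of_cohort,
        ).fit(X)
        genes = set(map(str, X.columns))
        cov = {}
        for sig in self.signatures:
            found = sum(1 for g in sig.genes if g in genes)
            if found == 0:
                raise ValueError(
                    f"signature {sig.name!r} has zero overlap with the matrix genes"
                )
            cov[sig.name] = found / len(sig.genes)
            if cov[sig.name] < self.min_coverage_warn:
                logger.warning(
                    "signature %r coverage %.2f below %.2f",
                    sig.name,
                    cov[sig.name],
                    self.min_coverage_warn,
                )
        self.coverage_ = pd.Series(cov, name="coverage")
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "zscorer_")
        z = self.zscorer_.transform(_as_frame(X))
        cols = {}
        for sig in self.signatures:
            up = [g for g in sig.up_set.genes if g in z.columns]
            down = (
                [g for g in sig.down_set.genes if g in z.columns]
                if sig.down_set is not None
                else []
            )
            score = z[up].sum(axis=1)
            if down:
                score = score - z[down].sum(axis=1)
            cols[sig.name] = score
        return pd.DataFrame(cols, index=z.index)


# ---------------------------------------------------------------------------
# Function layer over genes x samples frames (the on-disk orientation).
# ---------------------------------------------------------------------------

def compute_zscores(expr: pd.DataFrame, log_transform: bool = True) -> ZScoreResult:
    """Standardize a genes x samples abundance matrix across the cohort.

    Returns a :class:`ZScoreResult` holding z (genes x samples), per-gene
    mu/sigma, and the degenerate (sigma == 0) flags. sigma uses the n-1
    denominator; degenerate genes get all-zero z rows.
    """
    scorer = CohortZScorer(log_transform=log_transform).fit(expr.T)
    z = scorer.transform(expr.T).T
    return ZScoreResult(
        z=z,
        mu=pd.Series(scorer.mu_, index=expr.index, name="mu"),
        sigma=pd.Series(scorer.sigma_, index=expr.index, name="sigma"),
        degenerate=pd.Series(scorer.degenerate_, index=expr.index, name="degenerate"),
        log_transformed=log_transform,
    )


def score_signature(
    zres: ZScoreResult, sig: SignatureDefinition
) -> tuple[pd.Series, float]:
    """Score one signature; returns (per-sample score, gene coverage)."""
    z = zres.z
    up = [g for g in sig.up_set.genes if g in z.index]
    down = (
        [g for g in sig.down_set.genes if g in z.index]
        if sig.down_set is not None
        else []
    )
    found = len(up) + len(down)
    if found == 0:
        raise ValueError(
            f"signature {sig.name!r} has zero overlap with the matrix genes"
        )
    score = z.loc[up].sum(axis=0)
    if down:
        score = score - z.loc[down].sum(axis=0)
    score.name = sig.name
    return score, found / len(sig.genes)


def score_all(
    zres: ZScoreResult,
    sigs: Sequence[SignatureDefinition],
    min_coverage_warn: float = 0.5,
) -> ScoreTable:
    """Score every signature; coverage below ``min_coverage_warn`` is logged."""
    scores = {}
    coverage = {}
    for sig in sigs:
        s, cov = score_signature(zres, sig)
        scores[sig.name] = s
        coverage[sig.name] = cov
        if cov < min_coverage_warn:
            logger.warning("signature %r coverage %.2f", sig.name, cov)
    return ScoreTable(
        scores=pd.DataFrame(scores, index=zres.sample_ids),
        coverage=pd.Series(coverage, name="coverage"),
    )


def rank_and_segregate(
    scores: pd.Series, threshold: float = 0.0
) -> tuple[list[str], pd.Series]:
    """Rank samples by descending score and segregate at a threshold.

    Returns the ranked sample ids and a "high"/"low" label per sample
    (index order preserved). Samples exactly at the threshold are labelled
    "low" and logged.
    """
    values = scores.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = scores.index[~np.isfinite(values)][0]
        raise ValueError(f"non-finite score for sample {bad!r}")
    order = scores.sort_values(ascending=False, kind="stable").index.tolist()
    ties = int((values == threshold).sum())
    if ties:
        logger.info("%d sample(s) exactly at threshold %g labelled 'low'", ties, threshold)
    labels = pd.Series(
        np.where(values > threshold, "high", "low"), index=scores.index, name="label"
    )
    return order, labels


def dichotomize_gene(
    zres: ZScoreResult, gene: str, z_threshold: float = 1.0
) -> pd.Series:
    """Label samples "high" (z >= threshold) / "low" for one gene."""
    if gene not in zres.z.index:
        raise KeyError(f"gene {gene!r} not in the z-score matrix")
    if bool(zres.degenerate.loc[gene]):
        raise ValueError(
            f"gene {gene!r} has zero cohort variance; dichotomization undefined"
        )
    row = zres.z.loc[gene]
    return pd.Series(
        np.where(row.to_numpy() >= z_threshold, "high", "low"),
        index=row.index,
        name=f"{gene}_dichotomized",
    )
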