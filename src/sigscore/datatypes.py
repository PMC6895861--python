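"""Core domain containers: gene sets, signature definitions, validated tables.

Expression matrices are plain :class:`pandas.DataFrame` objects (genes as rows,
samples as columns) validated by :func:`validate_expression_matrix`; the small
structured objects (gene sets, signatures, z-score results, score tables) are
lightweight dataclasses around pandas containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "SignatureDefinition",
    "ZScoreResult",
    "ScoreTable",
    "validate_expression_matrix",
    "validate_annotations",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set must have a non-empty name")
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass(frozen=True)
class SignatureDefinition:
    """A signed signature: score = sum z(up_set) - sum z(down_set).

    ``down_set`` may be ``None`` for one-sided signatures (e.g. a pathway
    target-gene activity score).
    """

    name: str
    up_set: GeneSet
    down_set: GeneSet | None = None

    def __post_init__(self) -> None:
        if self.down_set is not None:
            overlap = set(self.up_set.genes) & set(self.down_set.genes)
            if overlap:
                raise ValueError(
                    f"signature {self.name!r}: up and down sets overlap: "
                    f"{sorted(overlap)[:5]}"
                )

    @property
    def genes(self) -> tuple[str, ...]:
        down = self.down_set.genes if self.down_set is not None else ()
        return self.up_set.genes + down

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ZScoreResult:
    """Per-gene cohort-standardized expression.

    Attributes
    ----------
    z : DataFrame, genes x samples
        Standardized values; rows of genes with zero cohort variance are all 0.
    mu, sigma : Series indexed by gene
        Cohort mean and (n-1 denominator) standard deviation on the scale the
        standardization was applied to (post log-transform if enabled).
    degenerate : Series of bool indexed by gene
        True where sigma == 0; those rows carry z == 0 everywhere.
    log_transformed : bool
        Whether a log2(x+1) transform preceded standardization.
    """

    z: pd.DataFrame
    mu: pd.Series
    sigma: pd.Series
    degenerate: pd.Series
    log_transformed: bool = False

    @property
    def gene_ids(self) -> pd.Index:
        return self.z.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.z.columns


@dataclass
class ScoreTable:
    """Sample x signature score values plus per-signature gene coverage."""

    scores: pd.DataFrame  # samples x signatures
    coverage: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def signature_names(self) -> pd.Index:
        return self.scores.columns


def validate_expression_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples abundance matrix.

    Requires unique gene and sample identifiers, a dense finite non-negative
    numeric body, and at least two samples (cohort standardization needs a
    cohort). Returns the validated frame (float dtype).
    """
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
    if expr.columns.duplicated().any():
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
    if expr.shape[1] < 2:
        raise ValueError(
            f"expression matrix has {expr.shape[1]} sample(s); at least 2 are "
            "required for cohort z-scores"
        )
    try:
        values = expr.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric value in expression matrix: {exc}") from exc
    if np.isnan(values).any():
        gi, si = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing value at gene {expr.index[gi]!r}, sample {expr.columns[si]!r}"
        )
    if not np.isfinite(values).all():
        gi, si = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite value at gene {expr.index[gi]!r}, sample {expr.columns[si]!r}"
        )
    if (values < 0).any():
        gi, si = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative abundance {values[gi, si]} at gene {expr.index[gi]!r}, "
            f"sample {expr.columns[si]!r}"
        )
    return expr.astype(float)


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-annotation table indexed by sample_id.

    Survival columns come as a pair: ``survival_time`` (days, > 0) together
    with ``event`` (boolean, True = death observed); having one without the
    other is an error. Unknown columns pass through untouched.
    """
    if ann.index.duplicated().any():
        dups = ann.index[ann.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample_id in annotations: {dups[:5]}")
    has_time = "survival_time" in ann.columns
    has_event = "event" in ann.columns
    if has_time != has_event:
        missing = "event" if has_time else "survival_time"
        raise ValueError(
            f"survival annotations require both survival_time and event; "
            f"{missing!r} is missing"
        )
    if has_time:
        times = pd.to_numeric(ann["survival_time"], errors="raise")
        if (times <= 0).any() or not np.isfinite(times).all():
            bad = ann.index[(times <= 0) | ~np.isfinite(times)][0]
            raise ValueError(f"survival_time must be finite and > 0 (sample {bad!r})")
        ann = ann.copy()
        ann["survival_time"] = times.astype(float)
        ann["event"] = ann["event"].astype(bool)
    return ann
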