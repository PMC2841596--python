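"""E-value based similarity model.

BLAST expectation values are mapped to evolutionary-relatedness
probabilities with a logistic regression on the transformed feature
``x = -log10(max(E, floor))``.  The posterior probability of the
"same family" class is the similarity score ``s_ij in (0, 1)``.
Scores for all observed pairs are assembled into a symmetric sparse
affinity matrix with a unit diagonal; when the two BLAST directions
disagree the smaller E-value (larger similarity) wins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "EValueRecord",
    "LogisticModel",
    "AffinityMatrix",
    "fit_logistic",
    "evalue_to_similarity",
    "build_affinity",
    "collapse_min_evalues",
    "default_model",
]

#: Default clamp applied before the log10 transform; BLAST reports
#: E = 0.0 for very strong hits and log(0) is undefined.
DEFAULT_EVALUE_FLOOR = 1e-180

#: Coefficients obtained by ``fit_logistic`` on the bundled synthetic
#: training set (``synthetic.generate_training_pairs`` with the default
#: spec and seed 0); rerun ``refit_default_model()`` to reproduce them.
DEFAULT_INTERCEPT = -37.459260
DEFAULT_SLOPE = 3.832804


class EValueRecord(NamedTuple):
    """One pairwise BLAST hit: query id, subject id, expectation value."""

    query_id: str
    subject_id: str
    evalue: float

    def validate(self) -> "EValueRecord":
        if not self.query_id or not self.subject_id:
            raise ValueError("sequence identifiers must be non-empty")
        if not (self.evalue >= 0):
            raise ValueError(f"E-value must be non-negative, got {self.evalue!r}")
        return self


@dataclass(frozen=True)
class LogisticModel:
    """Logistic map from E-values to relatedness probabilities.

    The similarity of an E-value ``E`` is ``sigmoid(a + b * x)`` with
    ``x = -log10(max(E, evalue_floor))``.  A positive slope ``b`` makes
    the similarity strictly decreasing in ``E``, as expected: smaller
    E-values indicate stronger evidence of homology.
    """

    intercept: float
    slope: float
    evalue_floor: float = DEFAULT_EVALUE_FLOOR

    def __post_init__(self) -> None:
        if not (self.evalue_floor > 0):
            raise ValueError("evalue_floor must be positive")
        if not (math.isfinite(self.intercept) and math.isfinite(self.slope)):
            raise ValueError("logistic coefficients must be finite")

    def feature(self, evalue) -> np.ndarray:
        """Transform E-values to the regression feature -log10(max(E, floor))."""
        e = np.asarray(evalue, dtype=float)
        if np.any(e < 0):
            raise ValueError("E-values must be non-negative")
        return -np.log10(np.maximum(e, self.evalue_floor))

    def similarity(self, evalue) -> np.ndarray:
        """Posterior probability of the intra-family class, in (0, 1).

        The sigmoid saturates in float64 for |a + b*x| > ~37, so the
        output is clipped just inside the open interval to keep the
        strict (0, 1) contract downstream code relies on.
        """
        from scipy.special import expit

        p = expit(self.intercept + self.slope * self.feature(evalue))
        return np.clip(p, 1e-300, 1.0 - 1e-16)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "evalue_floor": self.evalue_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            intercept=float(d["intercept"]),
            slope=float(d["slope"]),
            evalue_floor=float(d.get("evalue_floor", DEFAULT_EVALUE_FLOOR)),
        )


def default_model() -> LogisticModel:
    """Model shipped with the package, trained on the synthetic corpus."""
    return LogisticModel(DEFAULT_INTERCEPT, DEFAULT_SLOPE, DEFAULT_EVALUE_FLOOR)


def refit_default_model() -> LogisticModel:
    """Recompute the shipped default coefficients from scratch."""
    from specfam.synthetic import PlantedSpec, generate_training_pairs

    pairs = generate_training_pairs(PlantedSpec(seed=0))
    return fit_logistic(pairs)




def fit_logistic(
    labelled_pairs: Iterable[tuple[float, str]],
    evalue_floor: float = DEFAULT_EVALUE_FLOOR,
) -> LogisticModel:
    """Fit the E-value -> similarity logistic model by maximum likelihood.

    Parameters
    ----------
    labelled_pairs
        Iterable of ``(evalue, label)`` with label ``"intra"`` for pairs
        drawn from the same family and ``"inter"`` for pairs from
        different families.
    evalue_floor
        Clamp applied before the log10 transform.

    Returns
    -------
    LogisticModel
        Unpenalized maximum-likelihood fit (iteratively reweighted least
        squares) on ``x = -log10(max(E, floor))``, with the intra class
        coded as 1.

    Raises
    ------
    ValueError
        If only one class is present ("degenerate training set") or a
        label is not intra/inter.
    """
    import statsmodels.api as sm

    evalues, labels = [], []
    for evalue, label in labelled_pairs:
        if label not in ("intra", "inter"):
            raise ValueError(f"unknown label {label!r}; expected 'intra' or 'inter'")
        if not (evalue >= 0):
            raise ValueError("E-values must be non-negative")
        evalues.append(evalue)
        labels.append(1 if label == "intra" else 0)

    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: both intra and inter labels required")

    x = -np.log10(np.maximum(np.asarray(evalues, dtype=float), evalue_floor))
    design = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # IRLS separation chatter handled below
        result = sm.GLM(y.astype(float), design,
                        family=sm.families.Binomial()).fit(maxiter=200)
    intercept, slope = (float(v) for v in result.params)
    x1, x0 = x[y == 1], x[y == 0]
    if x1.min() > x0.max() or x1.max() < x0.min():  # disjoint feature ranges
        warnings.warn(
            "training classes are perfectly separated on the E-value feature; "
            "logistic coefficients are capped by the optimizer's iteration limit",
            RuntimeWarning,
            stacklevel=2,
        )
    return LogisticModel(intercept=intercept, slope=slope, evalue_floor=evalue_floor)


def evalue_to_similarity(model: LogisticModel, evalue) -> float | np.ndarray:
    """Similarity score of one E-value (or an array of them) under ``model``."""
    out = model.similarity(evalue)
    return float(out) if np.isscalar(evalue) else out


def collapse_min_evalues(
    records: Iterable[EValueRecord],
) -> tuple[list[str], dict[tuple[int, int], float]]:
    """Collapse records to the minimum E-value per unordered pair.

    Both reported directions and duplicate HSPs collapse onto one
    entry keyed by ``(i, j)`` with ``i < j`` (indices into the returned
    id list, ordered by first appearance).  Self hits are recorded as
    ids but contribute no pair entry.
    """
    ids: list[str] = []
    index: dict[str, int] = {}
    pairs: dict[tuple[int, int], float] = {}
    for rec in records:
        rec = EValueRecord(*rec).validate()
        for name in (rec.query_id, rec.subject_id):
            if name not in index:
                index[name] = len(ids)
                ids.append(name)
        i, j = index[rec.query_id], index[rec.subject_id]
        if i == j:
            continue
        key = (i, j) if i < j else (j, i)
        prev = pairs.get(key)
        if prev is None or rec.evalue < prev:
            pairs[key] = rec.evalue
    return ids, pairs


@dataclass
class AffinityMatrix:
    """Symmetric sparse matrix of similarity scores with a unit diagonal.

    ``matrix[i, j]`` holds ``s_ij in (0, 1]`` for pairs with a reported
    hit; absent pairs are structural zeros.  ``matrix[i, i] == 1`` for
    every sequence, regardless of the self-hit E-values in the input.
    """

    ids: list[str]
    matrix: sp.csr_array

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, seq_id: str) -> int:
        return self.ids.index(seq_id)

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def build_affinity(
    records: Sequence[EValueRecord], model: LogisticModel | None = None
) -> AffinityMatrix:
    """Assemble the symmetrized affinity matrix from pairwise hits.

    For every unordered pair the smallest E-value over both query
    directions and all HSPs is transformed with ``model``; the diagonal
    is forced to exactly 1.  Pairs never reported stay structurally
    absent (treated as zero similarity downstream).
    """
    if model is None:
        model = default_model()
    records = list(records)
    if not records:
        raise ValueError("no E-value records supplied")
    ids, pairs = collapse_min_evalues(records)
    n = len(ids)
    if pairs:
        keys = np.array(list(pairs.keys()), dtype=np.int64)
        vals = model.similarity(np.array(list(pairs.values()), dtype=float))
        rows = np.concatenate([keys[:, 0], keys[:, 1], np.arange(n)])
        cols = np.concatenate([keys[:, 1], keys[:, 0], np.arange(n)])
        data = np.concatenate([vals, vals, np.ones(n)])
    else:
        rows = cols = np.arange(n)
        data = np.ones(n)
    mat = sp.csr_array(sp.coo_array((data, (rows, cols)), shape=(n, n)))
    return AffinityMatrix(ids=ids, matrix=mat)
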