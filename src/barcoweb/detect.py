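"""Logistic model of molecular diet confirmation vs observed co-occurrence.

Every classified larva yields one binary outcome: was its fogged host
confirmed by the gut-content call?  The covariate is how often that
insect species was observed on that host species across the whole data
set — the premise being that frequently co-occurring pairs are real
feeding links while rare co-occurrences are often tourists.  The fitted
curve answers how many field observations a pair needs before the
observed association can be trusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class DetectionRecord:
    insect_species: str
    host_species: str
    occurrences: int          # observed co-occurrence count x >= 1
    confirmed: int            # y in {0, 1}
    body_size_mm: float | None = None

    def __post_init__(self) -> None:
        if self.occurrences < 1:
            raise ValueError("occurrence count must be a positive integer")
        if self.confirmed not in (0, 1):
            raise ValueError("confirmed must be 0 or 1")


def occurrence_counts(larvae, categories: dict[str, str]) -> list[DetectionRecord]:
    """One record per classified larva.

    x = total observed occurrences of the larva's insect species on its
    collection host across the data set; y = 1 iff the larva's mismatch
    category is ``match``.
    """
    classified = [l for l in larvae if l.larva_id in categories]
    pair_counts: dict[tuple[str, str], int] = {}
    for l in classified:
        key = (l.insect_species, l.collection_species)
        pair_counts[key] = pair_counts.get(key, 0) + 1
    return [
        DetectionRecord(
            insect_species=l.insect_species,
            host_species=l.collection_species,
            occurrences=pair_counts[(l.insect_species, l.collection_species)],
            confirmed=int(categories[l.larva_id] == "match"),
            body_size_mm=getattr(l, "body_size_mm", None),
        )
        for l in classified
    ]


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    intercept_p: float
    slope_p: float
    log_likelihood: float
    converged: bool
    covariate: str

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def fit_logistic(records: list[DetectionRecord],
                 covariate: str = "occurrences") -> LogisticFit:
    """Maximum-likelihood logistic regression of confirmation on a covariate.

    ``covariate`` is ``"occurrences"`` (the co-occurrence count) or
    ``"body_size_mm"``.  Raises on single-class outcomes or complete
    separation (no finite MLE exists there).
    """
    if covariate == "occurrences":
        x = np.array([r.occurrences for r in records], dtype=float)
    elif covariate == "body_size_mm":
        if any(r.body_size_mm is None for r in records):
            raise ValueError("body size missing for some records")
        x = np.array([r.body_size_mm for r in records], dtype=float)
    else:
        raise ValueError(f"unknown covariate: {covariate!r}")
    y = np.array([r.confirmed for r in records], dtype=float)
    if len(set(y)) < 2:
        raise ValueError("outcome has a single class; logistic fit undefined")
    X = sm.add_constant(x)
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200, tol=1e-8)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("logistic fit did not converge (separation?)")
    b0, b1 = res.params
    se0, se1 = res.bse
    p0, p1 = res.pvalues
    return LogisticFit(
        intercept=float(b0), slope=float(b1),
        intercept_se=float(se0), slope_se=float(se1),
        intercept_p=float(p0), slope_p=float(p1),
        log_likelihood=float(res.llf), converged=True, covariate=covariate,
    )


def predict_probability(fit, x) -> float | np.ndarray:
    """P(confirmed) = exp(b0 + b1*x) / (1 + exp(b0 + b1*x)).

    ``fit`` is a :class:`LogisticFit` or an ``(intercept, slope)`` pair.
    """
    if isinstance(fit, LogisticFit):
        b0, b1 = fit.intercept, fit.slope
    else:
        b0, b1 = fit
    z = b0 + b1 * np.asarray(x, dtype=float)
    p = 1.0 / (1.0 + np.exp(-z))
    return float(p) if np.isscalar(x) or np.asarray(x).ndim == 0 else p


def prediction_table(fit, x_max: int = 30) -> pd.DataFrame:
    xs = np.arange(1, x_max + 1)
    return pd.DataFrame({"occurrences": xs,
                         "p_confirmed": predict_probability(fit, xs)})
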