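"""Bayes-rule posterior classification from per-class DM likelihoods.

Given per-class DM parameters fitted from training data and a class prior
(either the empirical class frequencies or a user-supplied disease
prevalence), the posterior probability that a new count vector ``s`` belongs
to class ``C_i`` is

    Pr(C_i | s) = Pr(s | C_i) Pr(C_i) / sum_j Pr(s | C_j) Pr(C_j),

evaluated entirely in log space with a log-sum-exp normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .dm import DMParams, dm_log_pmf_rows

__all__ = ["ClassPrior", "Posterior", "empirical_prior", "posterior", "posterior_rows"]


@dataclass(frozen=True)
class ClassPrior:
    """Prior class probabilities, one per class label.

    ``source`` records whether the prior came from training-class frequencies
    (``"empirical"``) or was supplied by the user (``"user"``), e.g. as a
    known disease prevalence.
    """

    probs: np.ndarray
    source: str = "empirical"

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 1 or probs.size < 2:
            raise ValueError("prior needs one probability per class (>= 2 classes)")
        if np.any(probs <= 0.0) or np.any(probs >= 1.0):
            raise ValueError("degenerate prior: every class probability must lie strictly in (0, 1)")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"prior probabilities must sum to 1 (got {probs.sum()!r})")


@dataclass(frozen=True)
class Posterior:
    """Posterior class probabilities with the per-class log-likelihoods."""

    probs: np.ndarray
    log_likelihoods: np.ndarray


def empirical_prior(labels: np.ndarray, classes: np.ndarray | list | None = None) -> ClassPrior:
    """Prior from the relative frequency of each class in the training labels.

    ``classes`` fixes the ordering of the returned probabilities; by default
    classes are sorted. Every listed class must be present.
    """
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    classes = np.asarray(classes)
    counts = np.array([(labels == c).sum() for c in classes], dtype=float)
    if np.any(counts == 0):
        missing = [str(c) for c, k in zip(classes, counts) if k == 0]
        raise ValueError(f"class absent from training labels: {', '.join(missing)}")
    return ClassPrior(probs=counts / counts.sum(), source="empirical")


def posterior(s: np.ndarray, class_params: list[DMParams], prior: ClassPrior) -> Posterior:
    """Posterior class probabilities for one count vector (Bayes' rule)."""
    probs, logliks = posterior_rows(np.asarray(s)[None, :], class_params, prior)
    return Posterior(probs=probs[0], log_likelihoods=logliks[0])


def posterior_rows(
    counts: np.ndarray, class_params: list[DMParams], prior: ClassPrior
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized posterior over the rows of a count matrix.

    Returns ``(probs, log_likelihoods)`` of shapes (n, m) where m is the
    number of classes.
    """
    if len(class_params) != prior.probs.size:
        raise ValueError("prior length must match the number of classes")
    dims = {p.n_taxa for p in class_params}
    if len(dims) != 1:
        raise ValueError("all class parameter vectors must share the taxon dimension")
    logliks = np.column_stack([dm_log_pmf_rows(counts, p) for p in class_params])
    log_joint = logliks + np.log(prior.probs)
    probs = np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))
    return probs, logliks
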