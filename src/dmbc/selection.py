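"""Signature-taxon selection and the trained DMBC model.

The selection loop is the heart of the classifier:

1. rank every taxon by its two-sided Mann-Whitney P value comparing
   abundances between the two classes (no multiple-testing correction —
   the P values only order the taxa, they are not used for hypothesis
   testing);
2. for k = 1, 2, ... up to the number of taxa with P below the threshold
   (default 0.5, strict inequality), keep the top-k taxa individually and
   merge every other taxon into a single "other" column, preserving each
   sample's total read depth;
3. score each reduced dataset by leave-one-out cross-validated AUC of the
   diseased-class posterior probability;
4. keep the round with the highest AUC (ties broken toward the smallest k)
   and refit both classes' DM parameters on the full training data reduced
   to those signature taxa.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import mannwhitneyu

from .classify import ClassPrior, posterior_rows
from .dm import DMParams, FitResult, fit_dm, mom_params
from .io import LabeledTable

__all__ = [
    "TaxonRanking",
    "SelectionTrace",
    "TraceRound",
    "TrainedModel",
    "PredictionResult",
    "rank_taxa",
    "build_reduced",
    "loocv_auc",
    "select_features",
    "train",
    "predict",
    "save_model",
    "load_model",
    "model_to_json",
    "model_from_json",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: group-size bound under which the exact Mann-Whitney null is enumerated
EXACT_MW_MAX_N = 12


# ---------------------------------------------------------------------------
# Mann-Whitney ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonRanking:
    """Taxa ordered by ascending Mann-Whitney P value.

    ``pvalues`` is indexed by the original column order; ``order`` is the
    permutation that sorts it ascending (ties broken by the larger absolute
    difference in mean relative abundance, then by column order).
    """

    order: np.ndarray
    pvalues: np.ndarray
    candidate_count: int
    threshold: float


def _mw_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # tie-saturated: no separation at all
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    p = float(res.pvalue)
    if not np.isfinite(p):
        return 1.0
    return min(p, 1.0)


def rank_taxa(
    counts: np.ndarray,
    pos_mask: np.ndarray,
    threshold: float = 0.5,
    on_proportions: bool = False,
) -> TaxonRanking:
    """Rank taxa by two-sided Mann-Whitney P value between the two classes.

    Tested on raw counts by default; ``on_proportions`` rank-tests each
    taxon's relative abundance instead, which matters when sequencing depths
    differ strongly between samples.
    """
    counts = np.asarray(counts)
    pos_mask = np.asarray(pos_mask, dtype=bool)
    if counts.shape[1] < 2:
        raise ValueError("ranking needs at least 2 taxa")
    if pos_mask.sum() < 1 or (~pos_mask).sum() < 1:
        raise ValueError("both classes must be present to rank taxa")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"P-value threshold must lie in (0, 1], got {threshold!r}")
    values = counts.astype(float)
    if on_proportions:
        values = values / values.sum(axis=1, keepdims=True)
    pvals = np.array([_mw_pvalue(values[pos_mask, t], values[~pos_mask, t]) for t in range(counts.shape[1])])
    # tie-break: larger |difference in mean relative abundance| first, then column order
    rel = counts / counts.sum(axis=1, keepdims=True)
    absdiff = np.abs(rel[pos_mask].mean(axis=0) - rel[~pos_mask].mean(axis=0))
    order = np.lexsort((np.arange(counts.shape[1]), -absdiff, pvals))
    return TaxonRanking(
        order=order,
        pvalues=pvals,
        candidate_count=int((pvals < threshold).sum()),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# reduced dataset construction
# ---------------------------------------------------------------------------

def build_reduced(counts: np.ndarray, keep: np.ndarray | list[int]) -> np.ndarray:
    """Keep the listed taxon columns individually; merge the rest into one
    trailing "other" column.

    Row totals are preserved exactly; when ``keep`` covers every column the
    "other" column is structurally zero but still appended, so downstream
    fits always see k+1 columns.
    """
    counts = np.asarray(counts)
    keep = np.asarray(keep, dtype=int)
    if keep.size == 0:
        raise ValueError("keep must name at least one taxon column")
    if keep.size != np.unique(keep).size:
        raise ValueError("keep contains duplicate column indices")
    if keep.min() < 0 or keep.max() >= counts.shape[1]:
        raise ValueError("keep indices out of range")
    other = counts.sum(axis=1) - counts[:, keep].sum(axis=1)
    return np.column_stack([counts[:, keep], other])


# ---------------------------------------------------------------------------
# leave-one-out cross-validated AUC
# ---------------------------------------------------------------------------

def _fit_or_mom(counts: np.ndarray, alpha0: np.ndarray | None = None) -> FitResult:
    try:
        return fit_dm(counts, alpha0=alpha0)
    except (ValueError, FloatingPointError) as exc:  # degenerate fold: fall back to moments
        logger.warning("DM fit failed in a cross-validation fold (%s); using method-of-moments", exc)
        params = mom_params(counts)
        return FitResult(params=params, loglik=float("nan"), n_iter=0, converged=False)


def _fold_prior(pos_mask: np.ndarray, fixed: ClassPrior | None) -> ClassPrior:
    if fixed is not None:
        return fixed
    n_pos = int(pos_mask.sum())
    n = pos_mask.size
    return ClassPrior(probs=np.array([(n - n_pos) / n, n_pos / n]), source="empirical")


def loocv_auc(
    counts: np.ndarray,
    pos_mask: np.ndarray,
    keep: np.ndarray | list[int],
    prior: ClassPrior | None = None,
    rerank_k: int | None = None,
    rank_on_proportions: bool = False,
) -> tuple[float, np.ndarray]:
    """Leave-one-out cross-validated AUC on the reduced dataset.

    Each sample is scored by the diseased-class posterior from DM parameters
    fitted to all remaining samples; class order is (healthy, diseased).
    ``prior=None`` recomputes the empirical prior within each fold (the
    held-out sample is excluded); a fixed :class:`ClassPrior` overrides it.
    ``rerank_k`` switches to the strict mode that re-ranks taxa inside every
    fold (using only that fold's training rows) and keeps its own top-k.

    Returns ``(auc, scores)`` with one held-out score per sample.
    """
    from .roc import auc_rank

    counts = np.asarray(counts)
    pos_mask = np.asarray(pos_mask, dtype=bool)
    n = counts.shape[0]
    if min(pos_mask.sum(), (~pos_mask).sum()) < 3:
        raise ValueError(
            "leave-one-out needs at least 3 samples per class so every fold keeps >= 2; "
            "provide a larger training set"
        )
    if rerank_k is None:
        reduced = build_reduced(counts, keep)
        full_fits = {
            c: _fit_or_mom(reduced[pos_mask == c]) for c in (False, True)
        }
    scores = np.empty(n)
    for i in range(n):
        train_mask = np.ones(n, dtype=bool)
        train_mask[i] = False
        if rerank_k is not None:
            fold_ranking = rank_taxa(
                counts[train_mask], pos_mask[train_mask], on_proportions=rank_on_proportions
            )
            fold_keep = fold_ranking.order[:rerank_k]
            fold_reduced = build_reduced(counts, fold_keep)
            fits = {c: _fit_or_mom(fold_reduced[train_mask & (pos_mask == c)]) for c in (False, True)}
            held = fold_reduced[i]
        else:
            cls = bool(pos_mask[i])
            refit = _fit_or_mom(reduced[train_mask & (pos_mask == cls)], alpha0=full_fits[cls].params.alpha)
            fits = dict(full_fits)
            fits[cls] = refit
            held = reduced[i]
        fold_prior = _fold_prior(pos_mask[train_mask], prior)
        probs, _ = posterior_rows(held[None, :], [fits[False].params, fits[True].params], fold_prior)
        scores[i] = probs[0, 1]
    return auc_rank(scores, pos_mask.astype(int)), scores


# ---------------------------------------------------------------------------
# the selection loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceRound:
    k: int
    taxa: tuple[int, ...]
    auc: float


@dataclass(frozen=True)
class SelectionTrace:
    """Per-round record of the feature-selection loop."""

    rounds: tuple[TraceRound, ...]
    best_k: int
    threshold: float

    @property
    def best_round(self) -> TraceRound:
        for r in self.rounds:
            if r.k == self.best_k:
                return r
        raise RuntimeError("best_k not present in rounds")

    @property
    def best_auc(self) -> float:
        return self.best_round.auc


def select_features(
    counts: np.ndarray,
    pos_mask: np.ndarray,
    threshold: float = 0.5,
    prior: ClassPrior | None = None,
    rerank_per_fold: bool = False,
    rank_on_proportions: bool = False,
) -> SelectionTrace:
    """Run the iterated top-k + merged-remainder LOOCV-AUC loop.

    Rounds run k = 1 ... candidate_count where candidates are the taxa with
    Mann-Whitney P strictly below ``threshold``; the best round is the
    smallest k attaining the maximal AUC (parsimony tie-break).
    """
    ranking = rank_taxa(counts, pos_mask, threshold=threshold, on_proportions=rank_on_proportions)
    if ranking.candidate_count == 0:
        raise ValueError(
            f"no taxon has Mann-Whitney P < {threshold}; raise the threshold to admit candidates"
        )
    rounds = []
    for k in range(1, ranking.candidate_count + 1):
        keep = ranking.order[:k]
        auc, _ = loocv_auc(
            counts,
            pos_mask,
            keep,
            prior=prior,
            rerank_k=k if rerank_per_fold else None,
            rank_on_proportions=rank_on_proportions,
        )
        rounds.append(TraceRound(k=k, taxa=tuple(int(t) for t in keep), auc=auc))
    aucs = np.array([r.auc for r in rounds])
    best_k = rounds[int(np.argmax(aucs))].k  # first (smallest-k) maximum
    return SelectionTrace(rounds=tuple(rounds), best_k=best_k, threshold=threshold)


# ---------------------------------------------------------------------------
# trained model, prediction, persistence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainedModel:
    """Final DMBC model: per-class DM parameters over the signature taxa plus
    the merged "other" column, with the class prior and the selection trace."""

    signature_taxa: tuple[str, ...]
    classes: tuple[str, str]  # (healthy/negative, diseased/positive)
    class_params: tuple[DMParams, DMParams]  # same order as classes
    prior: ClassPrior
    trace: SelectionTrace
    threshold: float
    has_other_column: bool
    training_taxa: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    @property
    def positive_label(self) -> str:
        return self.classes[1]


@dataclass(frozen=True)
class PredictionResult:
    sample_ids: tuple[str, ...]
    probs: np.ndarray  # (n, 2) posterior, columns in model.classes order
    log_likelihoods: np.ndarray
    calls: tuple[str, ...]
    ties: np.ndarray  # flagged where the posterior was exactly 0.5/0.5


def _input_hash(table: LabeledTable) -> str:
    h = hashlib.sha256()
    h.update(table.counts.tobytes())
    h.update("\x00".join(str(x) for x in table.labels).encode())
    h.update("\x00".join(table.taxa).encode())
    h.update("\x00".join(table.sample_ids).encode())
    return h.hexdigest()


def train(
    table: LabeledTable,
    threshold: float = 0.5,
    prior: ClassPrior | tuple[float, float] | None = None,
    positive_label: str | None = None,
    rerank_per_fold: bool = False,
    rank_on_proportions: bool = False,
    seed: int = 0,
) -> TrainedModel:
    """Fit a DMBC model: select signature taxa, then estimate the final
    per-class DM parameters on the full training data.

    ``prior=None`` uses the empirical class frequencies; a pair of
    probabilities (healthy, diseased) supplies e.g. a known disease
    prevalence.  ``positive_label`` names the diseased class (default: the
    lexicographically second label).  ``seed`` is recorded in provenance;
    training itself is deterministic.
    """
    pos = table.positive_label(positive_label)
    neg = next(c for c in table.classes if c != pos)
    pos_mask = table.labels == pos
    if isinstance(prior, ClassPrior):
        fixed_prior: ClassPrior | None = prior
    elif prior is not None:
        fixed_prior = ClassPrior(probs=np.asarray(prior, dtype=float), source="user")
    else:
        fixed_prior = None

    trace = select_features(
        table.counts,
        pos_mask,
        threshold=threshold,
        prior=fixed_prior,
        rerank_per_fold=rerank_per_fold,
        rank_on_proportions=rank_on_proportions,
    )
    keep = np.asarray(trace.best_round.taxa, dtype=int)
    reduced = build_reduced(table.counts, keep)
    fits = {c: fit_dm(reduced[pos_mask == c]) for c in (False, True)}
    final_prior = fixed_prior if fixed_prior is not None else _fold_prior(pos_mask, None)
    from . import __version__

    return TrainedModel(
        signature_taxa=tuple(table.taxa[i] for i in keep),
        classes=(neg, pos),
        class_params=(fits[False].params, fits[True].params),
        prior=final_prior,
        trace=trace,
        threshold=threshold,
        has_other_column=True,
        training_taxa=tuple(table.taxa),
        provenance={
            "input_hash": _input_hash(table),
            "seed": int(seed),
            "package_version": __version__,
            "rerank_per_fold": rerank_per_fold,
            "rank_on_proportions": rank_on_proportions,
        },
    )


def map_to_model_columns(model: TrainedModel, counts: np.ndarray, taxa: list[str]) -> np.ndarray:
    """Map a new count table onto the model's (signature..., other) columns
    by taxon NAME; unmatched taxa are merged into "other", signature taxa
    absent from the new table contribute zero counts."""
    counts = np.asarray(counts)
    if not set(taxa) & set(model.training_taxa):
        raise ValueError(
            "no taxon-name overlap between the new table and the training taxa "
            "(is the table at the same taxonomy level?)"
        )
    col_of = {name: j for j, name in enumerate(taxa)}
    k = len(model.signature_taxa)
    out = np.zeros((counts.shape[0], k + 1), dtype=np.int64)
    matched = []
    for i, name in enumerate(model.signature_taxa):
        if name in col_of:
            out[:, i] = counts[:, col_of[name]]
            matched.append(col_of[name])
    other_cols = [j for j in range(counts.shape[1]) if j not in set(matched)]
    if other_cols:
        out[:, k] = counts[:, other_cols].sum(axis=1)
    return out


def predict(
    model: TrainedModel,
    counts: np.ndarray,
    taxa: list[str],
    sample_ids: list[str] | None = None,
) -> PredictionResult:
    """Posterior class probabilities and hard calls for new samples.

    Hard call is the argmax of the posterior; an exact tie is called diseased
    and flagged.
    """
    reduced = map_to_model_columns(model, counts, taxa)
    if np.any(reduced.sum(axis=1) == 0):
        raise ValueError("a sample has zero mapped reads; cannot score an empty count vector")
    probs, logliks = posterior_rows(reduced, list(model.class_params), model.prior)
    ties = probs[:, 1] == probs[:, 0]
    calls = tuple(
        model.classes[1] if (p1 >= p0) else model.classes[0] for p0, p1 in probs
    )
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(probs.shape[0])]
    if ties.any():
        logger.warning("%d sample(s) had an exact posterior tie; called diseased", int(ties.sum()))
    return PredictionResult(
        sample_ids=tuple(sample_ids),
        probs=probs,
        log_likelihoods=logliks,
        calls=calls,
        ties=ties,
    )


# ---------------------------------------------------------------------------
# JSON persistence (versioned schema)
# ---------------------------------------------------------------------------

def model_to_json(model: TrainedModel) -> str:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "signature_taxa": list(model.signature_taxa),
        "classes": list(model.classes),
        "class_params": {
            label: {"pi": [repr(float(x)) for x in params.pi], "theta": repr(float(params.theta))}
            for label, params in zip(model.classes, model.class_params)
        },
        "prior": {"probs": [repr(float(x)) for x in model.prior.probs], "source": model.prior.source},
        "threshold": model.threshold,
        "has_other_column": model.has_other_column,
        "training_taxa": list(model.training_taxa),
        "trace": {
            "threshold": model.trace.threshold,
            "best_k": model.trace.best_k,
            "rounds": [
                {"k": r.k, "taxa": list(r.taxa), "auc": repr(float(r.auc))} for r in model.trace.rounds
            ],
        },
        "provenance": model.provenance,
    }
    return json.dumps(payload, sort_keys=True, indent=1)


def model_from_json(text: str) -> TrainedModel:
    payload = json.loads(text)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {payload.get('schema_version')!r}")
    classes = tuple(payload["classes"])
    params = tuple(
        DMParams(
            pi=np.array([float(x) for x in payload["class_params"][label]["pi"]]),
            theta=float(payload["class_params"][label]["theta"]),
        )
        for label in classes
    )
    trace = SelectionTrace(
        rounds=tuple(
            TraceRound(k=r["k"], taxa=tuple(r["taxa"]), auc=float(r["auc"]))
            for r in payload["trace"]["rounds"]
        ),
        best_k=payload["trace"]["best_k"],
        threshold=payload["trace"]["threshold"],
    )
    return TrainedModel(
        signature_taxa=tuple(payload["signature_taxa"]),
        classes=classes,  # type: ignore[arg-type]
        class_params=params,  # type: ignore[arg-type]
        prior=ClassPrior(
            probs=np.array([float(x) for x in payload["prior"]["probs"]]),
            source=payload["prior"]["source"],
        ),
        trace=trace,
        threshold=payload["threshold"],
        has_other_column=payload["has_other_column"],
        training_taxa=tuple(payload["training_taxa"]),
        provenance=payload["provenance"],
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    Path(path).write_text(model_to_json(model), encoding="utf-8")


def load_model(path: str | Path) -> TrainedModel:
    return model_from_json(Path(path).read_text(encoding="utf-8"))
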