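"""Synthetic two-class DM count datasets with known ground truth.

The generator draws each sample's taxon proportions from a class-specific
Dirichlet distribution and its reads multinomially — the same compound
process the classifier models — so every stage of the pipeline can be
exercised with known compositions, overdispersions and signal taxa, without
any sequencing data.  Per-sample read depths are log-normal by default,
mimicking the uneven library sizes of real 16S runs (the classifier needs
no rarefaction, so depths are kept as drawn).

What it does NOT emulate: taxonomic mis-assignment, sparsity structure
beyond what the DM itself induces, or correlations between taxa that a
single Dirichlet cannot express.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dm import DMParams, dm_sample
from .io import LabeledTable

__all__ = ["SimulationSpec", "simulate", "planted_spec", "null_spec", "make_toy_table"]

HEALTHY, DISEASED = "healthy", "diseased"


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth description of a simulated two-class dataset.

    ``depth`` is either a fixed per-sample total read count or a pair
    ``("lognormal", geometric_mean, sigma)`` of the per-sample depth
    distribution.  ``signal_taxa`` (derived) are exactly the taxa whose
    expected proportions differ between the classes.
    """

    pi_healthy: np.ndarray
    pi_diseased: np.ndarray
    theta_healthy: float = 0.01
    theta_diseased: float = 0.01
    n_per_class: int = 25
    depth: int | tuple = ("lognormal", 2000, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi_healthy", "pi_diseased"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        # reuse DMParams validation for the compositions/overdispersions
        DMParams(pi=self.pi_healthy, theta=self.theta_healthy)
        DMParams(pi=self.pi_diseased, theta=self.theta_diseased)
        if self.pi_healthy.size != self.pi_diseased.size:
            raise ValueError("class compositions must cover the same taxa")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if isinstance(self.depth, tuple):
            if len(self.depth) != 3 or self.depth[0] != "lognormal":
                raise ValueError("depth must be an int or ('lognormal', geometric_mean, sigma)")
            if self.depth[1] < 1 or self.depth[2] < 0:
                raise ValueError("log-normal depth needs geometric mean >= 1 and sigma >= 0")
        elif int(self.depth) < 1:
            raise ValueError("fixed depth must be >= 1")

    @property
    def n_taxa(self) -> int:
        return self.pi_healthy.size

    @property
    def signal_taxa(self) -> tuple[int, ...]:
        diff = np.abs(self.pi_healthy - self.pi_diseased) > 1e-12
        return tuple(int(i) for i in np.flatnonzero(diff))

    def truth(self) -> dict:
        return {
            "pi_healthy": self.pi_healthy.tolist(),
            "pi_diseased": self.pi_diseased.tolist(),
            "theta_healthy": self.theta_healthy,
            "theta_diseased": self.theta_diseased,
            "n_per_class": self.n_per_class,
            "signal_taxa": list(self.signal_taxa),
            "seed": self.seed,
        }


def _draw_depths(spec: SimulationSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    if isinstance(spec.depth, tuple):
        _, gmean, sigma = spec.depth
        d = np.exp(rng.normal(np.log(gmean), sigma, size=n))
        return np.maximum(np.rint(d), 1).astype(np.int64)
    return np.full(n, int(spec.depth), dtype=np.int64)


def simulate(spec: SimulationSpec) -> tuple[LabeledTable, dict]:
    """Sample a labeled table per the spec; deterministic under its seed.

    Returns the table and the embedded ground-truth record.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = [f"taxon_{t + 1:03d}" for t in range(spec.n_taxa)]
    blocks, labels, ids = [], [], []
    for label, pi, theta in (
        (HEALTHY, spec.pi_healthy, spec.theta_healthy),
        (DISEASED, spec.pi_diseased, spec.theta_diseased),
    ):
        depths = _draw_depths(spec, rng, spec.n_per_class)
        block = dm_sample(DMParams(pi=pi, theta=theta), spec.n_per_class, depths, rng)
        # a zero-read sample cannot be scored; resample its rows (vanishingly rare)
        for i in np.flatnonzero(block.sum(axis=1) == 0):
            block[i] = dm_sample(DMParams(pi=pi, theta=theta), 1, max(int(depths[i]), 1), rng)[0]
        blocks.append(block)
        labels.extend([label] * spec.n_per_class)
        ids.extend([f"{label[0].upper()}{i + 1:03d}" for i in range(spec.n_per_class)])
    table = LabeledTable(
        sample_ids=ids,
        labels=np.array(labels, dtype=object),
        taxa=taxa,
        counts=np.vstack(blocks),
    )
    return table, spec.truth()


def planted_spec(
    n_taxa: int = 20,
    n_signal: int = 2,
    pi_high: float = 0.25,
    pi_low: float = 0.05,
    theta: float = 0.01,
    n_per_class: int = 25,
    depth: int | tuple = 2000,
    seed: int = 0,
) -> SimulationSpec:
    """Two-class spec with ``n_signal`` planted signal taxa.

    Signal taxa alternate between ``pi_high`` and ``pi_low`` across the two
    classes in balanced pairs (taxon 0 is high in healthy and low in
    diseased, taxon 1 the reverse, ...), so the remaining taxa share the
    same leftover mass in both classes and are genuinely null.  ``n_signal``
    must therefore be even.
    """
    if n_signal >= n_taxa:
        raise ValueError("need at least one non-signal taxon")
    if n_signal % 2:
        raise ValueError("n_signal must be even so non-signal taxa stay identical across classes")
    mass = n_signal // 2 * (pi_high + pi_low)
    pi_h = np.full(n_taxa, (1.0 - mass) / (n_taxa - n_signal))
    pi_d = pi_h.copy()
    for j in range(n_signal):
        pi_h[j] = pi_high if j % 2 == 0 else pi_low
        pi_d[j] = pi_low if j % 2 == 0 else pi_high
    return SimulationSpec(
        pi_healthy=pi_h,
        pi_diseased=pi_d,
        theta_healthy=theta,
        theta_diseased=theta,
        n_per_class=n_per_class,
        depth=depth,
        seed=seed,
    )


def null_spec(
    n_taxa: int = 20,
    theta: float = 0.01,
    n_per_class: int = 30,
    depth: int | tuple = 2000,
    seed: int = 0,
) -> SimulationSpec:
    """Identical class parameters: any apparent signal is noise."""
    rng = np.random.default_rng(12345)  # fixed composition shared by all null specs
    pi = rng.dirichlet(np.full(n_taxa, 5.0))
    pi = np.clip(pi, 1e-4, None)
    pi = pi / pi.sum()
    return SimulationSpec(
        pi_healthy=pi,
        pi_diseased=pi.copy(),
        theta_healthy=theta,
        theta_diseased=theta,
        n_per_class=n_per_class,
        depth=depth,
        seed=seed,
    )


def make_toy_table() -> LabeledTable:
    """Deterministic 6-sample, 4-taxon table used in the docs and tests."""
    taxa = ["Bacteroides", "Prevotella", "Faecalibacterium", "Ruminococcus"]
    counts = np.array(
        [
            [30, 5, 10, 5],
            [15, 12, 15, 8],
            [40, 3, 5, 2],
            [5, 25, 10, 10],
            [10, 40, 5, 5],
            [3, 20, 15, 12],
        ],
        dtype=np.int64,
    )
    return LabeledTable(
        sample_ids=["H001", "H002", "H003", "D001", "D002", "D003"],
        labels=np.array([HEALTHY] * 3 + [DISEASED] * 3, dtype=object),
        taxa=taxa,
        counts=counts,
    )
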