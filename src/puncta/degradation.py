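"""Probe detectability under RNA fragmentation.

An RNAscope target region tiles up to 20 adjacent double-Z probe-pair
sites along the transcript; a punctum becomes detectable when at least 3
consecutive pair sites survive on one fragment.  This module models
fragmentation at probe-pair granularity: each molecule receives a
Poisson-distributed number of breaks placed uniformly (with replacement)
among the ``n_pairs - 1`` junctions between adjacent sites, and the
molecule is detectable iff some fragment still carries a run of at least
``min_intact_run`` intact sites.  This captures why single-molecule FISH
tolerates partially degraded RNA that defeats qPCR amplification.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np


@dataclass
class DegradationModel:
    """Fragmentation model for one probe design.

    n_pairs
        Number of double-Z probe-pair sites tiled along the target (20 for
        a standard RNAscope probe).
    min_intact_run
        Consecutive intact sites required on one fragment for a detectable
        signal (3 for RNAscope amplification).
    expected_breaks
        Mean number of strand breaks per molecule (Poisson); the degradation
        severity dial.
    """

    n_pairs: int = 20
    min_intact_run: int = 3
    expected_breaks: float = 0.0
    n_molecules: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.min_intact_run < 1:
            raise ValueError("min_intact_run must be >= 1")
        if self.expected_breaks < 0:
            raise ValueError("expected_breaks must be non-negative")
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")


def _max_fragment(n_pairs: int, cuts: np.ndarray) -> int:
    """Longest run of intact sites given cut junction indices (0-based).

    Junction ``j`` separates sites ``j`` and ``j + 1``.
    """
    if cuts.size == 0:
        return n_pairs
    edges = np.concatenate(([-1], np.unique(cuts), [n_pairs - 1]))
    return int(np.diff(edges).max())


def simulate_detection_after_degradation(model: DegradationModel) -> float:
    """Monte-Carlo detectable fraction under Poisson fragmentation."""
    model.validate()
    if model.min_intact_run > model.n_pairs:
        return 0.0
    if model.n_pairs == 1:
        # no junctions to break: always one intact site
        return 1.0 if model.min_intact_run <= 1 else 0.0
    rng = np.random.default_rng(model.seed)
    n_junctions = model.n_pairs - 1
    breaks = rng.poisson(model.expected_breaks, model.n_molecules)
    detected = int(np.sum(breaks == 0))  # intact molecule: run = n_pairs
    for k in np.unique(breaks[breaks > 0]):
        idx = int(np.sum(breaks == k))
        cuts = np.sort(rng.integers(0, n_junctions, size=(idx, int(k))), axis=1)
        edges = np.concatenate(
            (
                np.full((idx, 1), -1, dtype=np.int64),
                cuts,
                np.full((idx, 1), model.n_pairs - 1, dtype=np.int64),
            ),
            axis=1,
        )
        max_frag = np.diff(edges, axis=1).max(axis=1)
        detected += int(np.sum(max_frag >= model.min_intact_run))
    return detected / model.n_molecules


def detection_probability_given_breaks(
    n_pairs: int, min_intact_run: int, n_breaks: int
) -> float:
    """Exact detectable probability given exactly ``n_breaks`` breaks.

    Exhaustive enumeration over all placements of the breaks (uniform iid
    with replacement over the ``n_pairs - 1`` junctions).  Intended for
    small ``n_pairs`` / ``n_breaks``; cost is ``(n_pairs - 1) ** n_breaks``.
    """
    if min_intact_run > n_pairs:
        return 0.0
    if n_breaks == 0:
        return 1.0
    if n_pairs == 1:
        return 1.0 if min_intact_run <= 1 else 0.0
    n_junctions = n_pairs - 1
    hits = 0
    total = 0
    for combo in product(range(n_junctions), repeat=n_breaks):
        total += 1
        if _max_fragment(n_pairs, np.asarray(combo)) >= min_intact_run:
            hits += 1
    return hits / total


def detection_probability(
    n_pairs: int, min_intact_run: int, expected_breaks: float
) -> float:
    """Exact detectable probability under the Poisson mixture.

    Poisson(λ) breaks placed iid uniformly over J = n_pairs - 1 junctions
    thin into independent Poisson(λ/J) counts per junction, so each junction
    is cut independently with probability q = 1 - exp(-λ/J).  A run-length
    recursion then gives P(no fragment reaches the minimum run):

        A(0) = 1,
        A(m) = Σ_{l=1}^{min(m, r-1)} (1-q)^{l-1} · [q·A(m-l) if l < m else 1]

    and the detectable probability is 1 - A(n_pairs).  Serves as the
    independent closed-form check for the Monte-Carlo simulator.
    """
    if min_intact_run > n_pairs:
        return 0.0
    if expected_breaks == 0 or n_pairs == 1:
        return 1.0
    r = min_intact_run
    q = 1.0 - np.exp(-expected_breaks / (n_pairs - 1))
    a = np.zeros(n_pairs + 1)
    a[0] = 1.0
    for m in range(1, n_pairs + 1):
        acc = 0.0
        for length in range(1, min(m, r - 1) + 1):
            if length < m:
                acc += (1 - q) ** (length - 1) * q * a[m - length]
            else:  # the whole remaining molecule is one fragment
                acc += (1 - q) ** (length - 1)
        a[m] = acc
    return float(1.0 - a[n_pairs])
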