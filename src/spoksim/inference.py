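"""Estimators operating on observed or simulated ascus counts.

The observable of a *Podospora* cross is the count vector (n2, n3, n4) of
two-, three- and four-spored asci.  With a single heteroallelic killer,
(P2, P3, P4) = (f·q², 2·f·q·(1−q), rest) for FDS probability f and per-spore
penetrance q, which yields a closed-form trinomial maximum-likelihood
estimator of (f, q).  Zero-spored asci are excluded: they are uncountable in
practice and the study never tabulates them in percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class AscusCountData:
    """Counts of two-, three- and four-spored asci from one cross."""

    n2: int
    n3: int
    n4: int

    def __post_init__(self):
        if min(self.n2, self.n3, self.n4) < 0:
            raise ValueError("counts must be non-negative")
        if self.N < 1:
            raise ValueError("at least one ascus required")

    @property
    def N(self) -> int:
        return self.n2 + self.n3 + self.n4


def killing_percentage(counts: AscusCountData, policy: str = "exclude3",
                       decimals: int | None = None) -> float:
    """Spore-killing percentage of a cross (two-spored asci share).

    ``exclude3`` (the study's policy — three-spored asci "were excluded from
    the analyses"): 100·n2/(n2+n4).  ``include3``: 100·n2/N.  ``decimals``
    optionally rounds to the study's one-decimal reporting.
    """
    if policy == "exclude3":
        denom = counts.n2 + counts.n4
    elif policy == "include3":
        denom = counts.N
    else:
        raise ValueError(f"unknown policy {policy!r}")
    if denom == 0:
        raise ValueError("zero denominator: no countable asci under policy")
    pct = 100.0 * counts.n2 / denom
    return round(pct, decimals) if decimals is not None else pct


def ascus_class_percentages(counts: AscusCountData) -> dict:
    """Percentage of each countable ascus class among all N asci."""
    return {k: 100.0 * v / counts.N
            for k, v in ((2, counts.n2), (3, counts.n3), (4, counts.n4))}


def estimate_fds_penetrance(counts: AscusCountData) -> Tuple[float, float]:
    """Closed-form trinomial MLE of (FDS probability f, penetrance q).

    q̂ = 2·n2/(2·n2+n3) and f̂ = (n2+n3)/(N·q̂·(2−q̂)); this inverts the
    expected class distribution exactly on noiseless expected counts.  f̂ is
    clipped to (0, 1] with a warning when the counts imply f > 1.
    """
    n2, n3, N = counts.n2, counts.n3, counts.N
    if n2 + n3 == 0:
        raise ValueError("n2 = n3 = 0: (f, q) unidentifiable "
                         "(no killing signal in the data)")
    if n2 == 0:
        # all partial killing: q -> 0 limit; f only bounded below
        q_hat = 0.0
        f_hat = 1.0
        warnings.warn("n2 = 0 implies q̂ = 0; f is unidentified and clipped "
                      "to 1", stacklevel=2)
        return f_hat, q_hat
    q_hat = 2.0 * n2 / (2.0 * n2 + n3)
    f_hat = (n2 + n3) / (N * q_hat * (2.0 - q_hat))
    if f_hat > 1.0:
        warnings.warn(f"counts imply f̂ = {f_hat:.4f} > 1; clipping to 1",
                      stacklevel=2)
        f_hat = 1.0
    return f_hat, q_hat


def binomial_consistency(n2: int, N: int, p_model: float) -> float:
    """Exact two-sided binomial p-value of ``n2`` successes out of ``N``.

    Used to reconcile printed ascus counts with a model success probability.
    Degenerate ``p_model`` in {0, 1} is handled analytically: probability 1
    iff the counts match exactly, else 0.
    """
    if not (0 <= n2 <= N):
        raise ValueError("need 0 <= n2 <= N")
    if p_model <= 0.0:
        return 1.0 if n2 == 0 else 0.0
    if p_model >= 1.0:
        return 1.0 if n2 == N else 0.0
    return float(stats.binomtest(n2, N, p_model).pvalue)


def consistent_with_success_probability(n2: int, N: int, p_floor: float,
                                        alpha: float = 0.05) -> bool:
    """Is the count consistent with some success probability ≥ ``p_floor``?

    The composite hypothesis p ≥ p_floor is retained when any p on a grid of
    [p_floor, 1) gives an exact two-sided p-value above ``alpha``.
    """
    grid = np.linspace(p_floor, 1.0 - 1e-4, 50)
    return any(binomial_consistency(n2, N, p) > alpha for p in grid)
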