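"""Random-effects pooling of network-specific standardized rates.

DerSimonian-Laird estimation on the log-rate scale with normal-quantile
confidence intervals (no Knapp-Hartung adjustment).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

Z_975 = 1.959963984540054


@dataclass(frozen=True)
class MetaInput:
    """One network's contribution: log standardized rate and its SE."""

    network: str
    y: float
    se: float

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"se must be positive, got {self.se} ({self.network})")


@dataclass(frozen=True)
class MetaResult:
    pooled: float       # per 1,000
    ci_lo: float        # per 1,000
    ci_hi: float        # per 1,000
    tau2: float         # between-network variance, log scale
    q_stat: float
    k: int

    def __post_init__(self):
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if not (self.ci_lo <= self.pooled <= self.ci_hi):
            raise ValueError("CI must bracket the pooled estimate")


def dl_meta(inputs: Sequence[MetaInput], use_knapp_hartung: bool = False) -> MetaResult:
    """Pool log rates by the DerSimonian-Laird random-effects model.

    ``y`` values are logs of rates per 1 (person-year or proportion); the
    pooled result and CI are reported per 1,000.  With a single input the
    estimate passes through with tau2 = Q = 0.
    """
    if use_knapp_hartung:
        raise NotImplementedError("Knapp-Hartung adjustment is not provided")
    k = len(inputs)
    if k == 0:
        raise ValueError("dl_meta needs at least one input")
    y = np.array([m.y for m in inputs], dtype=float)
    se = np.array([m.se for m in inputs], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")

    w = 1.0 / se**2
    y_fixed = float(np.sum(w * y) / np.sum(w))
    q_stat = float(np.sum(w * (y - y_fixed) ** 2)) if k > 1 else 0.0
    if k == 1:
        tau2 = 0.0
    else:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q_stat - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled_log = float(np.sum(w_star * y) / np.sum(w_star))
    se_star = float(np.sum(w_star) ** -0.5)
    return MetaResult(
        pooled=1000.0 * math.exp(pooled_log),
        ci_lo=1000.0 * math.exp(pooled_log - Z_975 * se_star),
        ci_hi=1000.0 * math.exp(pooled_log + Z_975 * se_star),
        tau2=float(tau2),
        q_stat=q_stat,
        k=k,
    )


def pool_networks(estimates: Sequence[tuple[str, float, float, bool]]) -> MetaResult:
    """Pool (network, rate_per_1000, se_log, converged) tuples, excluding
    networks whose fit did not converge reliably (exclusions are logged)."""
    usable = []
    for network, rate, se_log, converged in estimates:
        if not converged:
            logger.warning("excluding network %s from pooling: convergence not reliable",
                           network)
            continue
        if rate <= 0:
            logger.warning("excluding network %s from pooling: non-positive rate", network)
            continue
        usable.append(MetaInput(network=network, y=math.log(rate / 1000.0), se=se_log))
    if not usable:
        raise ValueError("no networks eligible for pooling")
    return dl_meta(usable)
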