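"""Fixed-effect and DerSimonian-Laird random-effects meta-analysis."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class StudyEffect:
    """One study's effect estimate (per 5% methylation) and its SE."""

    study: str
    beta: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")


@dataclass
class MetaResult:
    pooled_beta: float
    pooled_se: float
    p: float
    Q: float
    tau2: float
    I2: float
    model: str
    n_studies: int


def _heterogeneity(betas: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    pooled = float(np.sum(weights * betas) / np.sum(weights))
    Q = float(np.sum(weights * (betas - pooled) ** 2))
    return pooled, Q


def fixed_effect(effects: list[StudyEffect]) -> MetaResult:
    """Inverse-variance fixed-effect pooling."""
    if not effects:
        raise ValueError("at least one study is required")
    betas = np.array([e.beta for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    pooled, Q = _heterogeneity(betas, w)
    se = 1.0 / math.sqrt(w.sum())
    df = len(effects) - 1
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(pooled / se))
    return MetaResult(
        pooled_beta=pooled, pooled_se=se, p=float(p), Q=Q, tau2=0.0, I2=I2,
        model="fixed", n_studies=len(effects),
    )


def dersimonian_laird(effects: list[StudyEffect]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling with Q, tau^2, I^2.

    ``tau2 = max(0, (Q - df) / C)`` with ``C = sum(w) - sum(w^2)/sum(w)``
    from the fixed-effect weights; the pooled p-value uses a normal
    reference (optimistic for very few studies).
    """
    if len(effects) < 2:
        raise ValueError("random-effects pooling needs at least 2 studies")
    betas = np.array([e.beta for e in effects])
    v = np.array([e.se**2 for e in effects])
    w = 1.0 / v
    _, Q = _heterogeneity(betas, w)
    df = len(effects) - 1
    C = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - df) / C)
    wr = 1.0 / (v + tau2)
    pooled = float(np.sum(wr * betas) / wr.sum())
    se = 1.0 / math.sqrt(wr.sum())
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(pooled / se))
    return MetaResult(
        pooled_beta=pooled, pooled_se=se, p=float(p), Q=float(Q), tau2=float(tau2),
        I2=float(I2), model="random", n_studies=len(effects),
    )
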