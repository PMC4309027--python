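"""Decoy-based significance assessment with Bonferroni correction.

The per-test critical value is alpha_whole / K, where K is the number of
target peptide entries in the composite database.  P(S >= s) under the
null is estimated from the per-spectrum decoy score distribution, either
as an add-one-smoothed empirical tail fraction or by a moment-fitted
Gumbel right tail (the default, since the empirical estimator cannot
reach the very small Bonferroni-corrected critical values with realistic
decoy-list sizes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .search import Hit

EULER_GAMMA = 0.5772156649015329
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class SignificanceConfig:
    alpha_whole: float = 0.05
    K: int = 1
    pvalue_mode: str = "gumbel"  # "empirical" | "gumbel"

    def __post_init__(self) -> None:
        if not 0 < self.alpha_whole < 1:
            raise ValueError("alpha_whole must be in (0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.pvalue_mode not in ("empirical", "gumbel"):
            raise ValueError("pvalue_mode must be 'empirical' or 'gumbel'")

    @property
    def alpha(self) -> float:
        return bonferroni_alpha(self.alpha_whole, self.K)


def bonferroni_alpha(alpha_whole: float, K: int) -> float:
    """Per-test critical value alpha_whole / K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return alpha_whole / K


def empirical_pvalue(score: float, decoy_scores: Sequence[float]) -> float:
    """Add-one-smoothed empirical tail probability.

    p = (1 + #{d >= s}) / (1 + N); ties with decoy scores count against
    the hit.  p is in (0, 1] and equals 1 for an empty decoy list.
    """
    n_ge = sum(1 for d in decoy_scores if d >= score)
    return (1 + n_ge) / (1 + len(decoy_scores))


def gumbel_pvalue(score: float, decoy_scores: Sequence[float]) -> float:
    """Right-tail probability under a Gumbel fit to the decoy scores.

    Location/scale by the method of moments; falls back to the empirical
    estimator when the decoy list is too small or degenerate to fit.
    """
    n = len(decoy_scores)
    if n < 3:
        return empirical_pvalue(score, decoy_scores)
    mean = sum(decoy_scores) / n
    var = sum((d - mean) ** 2 for d in decoy_scores) / (n - 1)
    if var <= 0:
        return empirical_pvalue(score, decoy_scores)
    beta = math.sqrt(6.0 * var) / math.pi
    mu = mean - EULER_GAMMA * beta
    z = (score - mu) / beta
    # P(S >= s) = 1 - exp(-exp(-z)); -expm1 keeps precision in the far tail
    if z > 700:
        return _P_FLOOR
    p = -math.expm1(-math.exp(-z))
    return max(p, _P_FLOOR)


def pvalue(score: float, decoy_scores: Sequence[float], mode: str = "gumbel") -> float:
    if mode == "empirical":
        return empirical_pvalue(score, decoy_scores)
    if mode == "gumbel":
        return gumbel_pvalue(score, decoy_scores)
    raise ValueError(f"unknown pvalue mode {mode!r}")


def annotate_pvalues(
    target_hits: Sequence[Hit],
    decoy_scores: Sequence[float],
    config: SignificanceConfig,
) -> None:
    """Fill ``p_value`` on every target hit in place."""
    for hit in target_hits:
        hit.p_value = pvalue(hit.score, decoy_scores, config.pvalue_mode)


def filter_significant(
    target_hits: Sequence[Hit],
    decoy_scores: Sequence[float],
    config: SignificanceConfig,
) -> list[Hit]:
    """Hits with p strictly below the Bonferroni-corrected alpha.

    Annotates p-values on all hits and returns the significant subset with
    the input ordering preserved.
    """
    annotate_pvalues(target_hits, decoy_scores, config)
    alpha = config.alpha
    return [h for h in target_hits if h.p_value is not None and h.p_value < alpha]
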