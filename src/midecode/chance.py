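"""Above-chance significance of classification accuracies.

For a pairwise classification evaluated on ``N`` pooled test segments the
baseline is the *maximum chance criterion* ``HC`` — the size of the larger
class, i.e. the number of correct answers obtainable by always guessing the
majority condition.  A correct count ``H0`` is declared above chance when the
z-statistic

    z = (H0 - HC) / sqrt(HC * (N - HC) / N)

exceeds the standard-normal critical value for the chosen alpha level
(two-sided by default).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "ChanceCriterion",
    "z_statistic",
    "critical_count",
    "bonferroni_alpha",
    "chance_criterion",
]


def z_statistic(h0: int, hc: int, n: int) -> float:
    """z-score of ``h0`` correct out of ``n`` against the maximum chance count ``hc``.

    Parameters
    ----------
    h0 : number of correctly classified test segments, 0 <= h0 <= n.
    hc : maximum chance criterion (the larger class size), 0 < hc < n.
    n : total number of test segments.
    """
    if not 0 <= h0 <= n:
        raise ValueError(f"h0 must lie in [0, {n}], got {h0}")
    if not 0 < hc < n:
        raise ValueError(f"hc must lie strictly between 0 and {n}, got {hc}")
    return (h0 - hc) / (hc * (n - hc) / n) ** 0.5


def critical_count(
    hc: int, n: int, alpha: float = 0.05, two_sided: bool = True
) -> int:
    """Smallest integer correct count whose z-statistic is significant.

    Returns the minimal ``h0`` with ``z_statistic(h0, hc, n)`` strictly above
    the standard-normal critical value for ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z_crit = norm.ppf(1 - alpha / 2) if two_sided else norm.ppf(1 - alpha)
    # z > z_crit  <=>  h0 > hc + z_crit * sqrt(hc (n - hc) / n)
    import math

    bound = hc + z_crit * (hc * (n - hc) / n) ** 0.5
    h0 = math.floor(bound) + 1
    return min(h0, n)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test alpha level."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass(frozen=True)
class ChanceCriterion:
    """Summary of the above-chance decision rule for one test-set geometry."""

    n: int
    hc: int
    alpha: float
    two_sided: bool
    z_critical: float
    critical_count: int
    critical_accuracy: float

    def is_significant(self, h0: int) -> bool:
        return h0 >= self.critical_count


def chance_criterion(
    n: int, hc: int, alpha: float = 0.05, two_sided: bool = True
) -> ChanceCriterion:
    """Build the full decision rule for ``n`` test segments with chance count ``hc``."""
    if hc > n:
        raise ValueError("hc cannot exceed n")
    z_crit = float(norm.ppf(1 - alpha / 2) if two_sided else norm.ppf(1 - alpha))
    count = critical_count(hc, n, alpha, two_sided)
    return ChanceCriterion(
        n=n,
        hc=hc,
        alpha=alpha,
        two_sided=two_sided,
        z_critical=z_crit,
        critical_count=count,
        critical_accuracy=count / n,
    )
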