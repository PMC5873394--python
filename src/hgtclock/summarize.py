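"""Burn-in, medians, HPD intervals, and transfer-feasibility probabilities.

The quantities reported by a dating analysis are, per node of interest, the
posterior median age and a 95% highest-posterior-density (HPD) interval — the
shortest interval containing 95% of the retained samples — plus, for transfer
hypotheses, P(age A > age B) evaluated over the (optionally HGT-filtered)
posterior.

The empirical HPD estimator used here is the standard shortest-window search
over consecutive order statistics: with n sorted ages and k = ceil(level*n),
scan the n-k+1 windows [x_(i), x_(i+k-1)] and return the narrowest, breaking
ties by the lowest lower bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .chronotree import AgeTrace, ChronogramTrace, CladeDefinition, clade_age_trace
from .errors import HgtClockError, InsufficientSamplesError, PairingError

__all__ = [
    "SummaryRow",
    "HypothesisResult",
    "apply_burn_in",
    "hpd_interval",
    "median_age",
    "prob_older",
    "summarize_model",
    "hpd_width_reduction",
    "summary_table_tsv",
    "hypothesis_table_tsv",
]


@dataclass(frozen=True)
class SummaryRow:
    """Median + HPD summary for one named node (one table row)."""

    node: str
    n: int
    median: float
    hpd_lower: float
    hpd_upper: float
    level: float = 0.95

    def __post_init__(self):
        if self.n < 1:
            raise InsufficientSamplesError(f"row {self.node!r}: no samples")
        if not (self.hpd_lower <= self.median <= self.hpd_upper):
            raise ValueError(
                f"row {self.node!r}: HPD ({self.hpd_lower}, {self.hpd_upper}) "
                f"does not bracket median {self.median}"
            )

    @property
    def hpd_width(self) -> float:
        return self.hpd_upper - self.hpd_lower


@dataclass(frozen=True)
class HypothesisResult:
    """P(age A > age B) with the sample and tie counts behind it."""

    name: str
    node_a: str
    node_b: str
    probability: float
    n: int
    ties: int

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability outside [0, 1]")


def apply_burn_in(
    trace: ChronogramTrace, fraction: float = 0.2, *, force: bool = False
) -> ChronogramTrace:
    """Drop the first floor(fraction * N) saved points of a trace.

    N is the saved-point count recorded at parse time, so re-application would
    trim twice; a second call is therefore refused unless ``force=True``.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"burn-in fraction must be in [0, 1), got {fraction}")
    if trace.burn_in_applied and not force:
        raise ValueError(
            f"burn-in already applied to {trace.source!r}; pass force=True to re-trim"
        )
    n_drop = math.floor(fraction * trace.n_saved)
    return replace(
        trace,
        samples=trace.samples[n_drop:],
        burn_in_applied=True,
        burn_in_fraction=fraction,
    )


def _as_array(ages) -> np.ndarray:
    if isinstance(ages, AgeTrace):
        return ages.ages
    return np.asarray(ages, dtype=float)


def hpd_interval(ages, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval of consecutive order statistics holding ceil(level*n)
    samples; ties broken toward the lowest lower bound."""
    x = np.sort(_as_array(ages))
    n = len(x)
    if n < 2:
        raise InsufficientSamplesError(f"HPD needs at least 2 samples, got {n}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"HPD level must be in (0, 1), got {level}")
    k = math.ceil(level * n)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest lower bound
    return float(x[i]), float(x[i + k - 1])


def median_age(ages) -> float:
    """Sample median (mean of the two central order statistics for even n)."""
    x = _as_array(ages)
    if len(x) == 0:
        raise InsufficientSamplesError("median of an empty age trace")
    return float(np.median(x))


def prob_older(
    ages_a,
    ages_b,
    *,
    paired: bool = True,
    name: str = "",
    node_a: str = "",
    node_b: str = "",
) -> HypothesisResult:
    """P(age A > age B), with ties counted separately and excluded from the
    numerator.

    Paired mode (default) walks the two traces in lockstep — appropriate when
    both ages come from the same posterior samples.  Unpaired mode forms the
    cross-product estimate over all (a, b) pairs, for independent traces; it
    is computed by sorting, in O(n log n).
    """
    a, b = _as_array(ages_a), _as_array(ages_b)
    if isinstance(ages_a, AgeTrace) and not node_a:
        node_a = ages_a.name
    if isinstance(ages_b, AgeTrace) and not node_b:
        node_b = ages_b.name
    if len(a) == 0 or len(b) == 0:
        raise InsufficientSamplesError("prob_older needs non-empty age traces")
    if paired:
        if len(a) != len(b):
            raise PairingError(
                f"paired mode requires equal lengths, got {len(a)} vs {len(b)}"
            )
        wins = int(np.sum(a > b))
        ties = int(np.sum(a == b))
        n = len(a)
        prob = wins / n
    else:
        sorted_b = np.sort(b)
        # pairs with b strictly below a, and exact-tie pairs
        below = np.searchsorted(sorted_b, a, side="left")
        at_or_below = np.searchsorted(sorted_b, a, side="right")
        wins = int(below.sum())
        ties = int((at_or_below - below).sum())
        n = len(a) * len(b)
        prob = wins / n
    return HypothesisResult(
        name=name or f"P({node_a or 'A'} > {node_b or 'B'})",
        node_a=node_a or "A",
        node_b=node_b or "B",
        probability=prob,
        n=n,
        ties=ties,
    )


def summarize_model(
    trace: ChronogramTrace,
    clade_definitions: Sequence[CladeDefinition],
    level: float = 0.95,
    *,
    strict: bool = True,
) -> list[SummaryRow]:
    """One summary row per clade definition, in input order.

    Per-clade failures (unknown leaf, non-monophyly, stem-of-root) are
    collected and reported together rather than aborting on the first.
    """
    rows: list[SummaryRow] = []
    failures: list[str] = []
    for clade in clade_definitions:
        try:
            ages = clade_age_trace(trace, clade, strict=strict)
            lower, upper = hpd_interval(ages, level)
            rows.append(
                SummaryRow(
                    node=ages.name,
                    n=len(ages),
                    median=median_age(ages),
                    hpd_lower=lower,
                    hpd_upper=upper,
                    level=level,
                )
            )
        except HgtClockError as exc:
            failures.append(f"{clade.selector} {clade.name}: {exc}")
    if failures:
        raise HgtClockError(
            "summarize_model failed for "
            f"{len(failures)} clade(s):\n  " + "\n  ".join(failures)
        )
    return rows


def hpd_width_reduction(unconstrained: SummaryRow, constrained: SummaryRow) -> float:
    """Percent narrowing of the HPD interval, 100 * (1 - w_c / w_u).

    Negative when the constrained interval widened.  Undefined (error) for a
    zero-width unconstrained interval.
    """
    if unconstrained.level != constrained.level:
        raise ValueError(
            f"HPD levels differ: {unconstrained.level} vs {constrained.level}"
        )
    if unconstrained.hpd_width == 0.0:
        raise ValueError(
            f"node {unconstrained.node!r}: zero-width unconstrained HPD; "
            "width reduction undefined"
        )
    return 100.0 * (1.0 - constrained.hpd_width / unconstrained.hpd_width)


# -- TSV rendering ---------------------------------------------------------


def summary_table_tsv(rows: Sequence[SummaryRow]) -> str:
    lines = ["node\tn\tmedian_Ma\thpd_lower_Ma\thpd_upper_Ma\tlevel"]
    for r in rows:
        lines.append(
            f"{r.node}\t{r.n}\t{r.median:.6g}\t{r.hpd_lower:.6g}\t{r.hpd_upper:.6g}\t{r.level:g}"
        )
    return "\n".join(lines) + "\n"


def hypothesis_table_tsv(results: Sequence[HypothesisResult]) -> str:
    lines = ["name\tnodeA\tnodeB\tprobability\tn\tties"]
    for h in results:
        lines.append(
            f"{h.name}\t{h.node_a}\t{h.node_b}\t{h.probability:.6g}\t{h.n}\t{h.ties}"
        )
    return "\n".join(lines) + "\n"
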