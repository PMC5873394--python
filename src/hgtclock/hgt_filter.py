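"""Relative time constraints from horizontal gene transfers, and posterior
conditional post-sampling.

A gene transfer observed between two clades orders their nodes in time: the
donor's node must be older than the recipient's.  Applied to a posterior
trace of dated trees, the constraint acts as rejection filtering — keep
exactly the MCMC samples in which every transfer's age ordering holds.  The
filtered sample set is the posterior conditional on the transfer constraints,
so medians and HPD intervals computed from it are the constrained estimates.

Defaults follow the weakest safe reading of a transfer "from within" a donor
clade into a recipient's stem: donor node = donor crown (the transfer
postdates the donor's crown radiation), recipient node = recipient crown (a
transfer into the stem predates the crown).  Both are overridable per
constraint via the clade selectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .chronotree import Chronogram, ChronogramTrace, CladeDefinition, resolve_node
from .errors import FormatError, HgtClockError, InvalidConstraintError

__all__ = [
    "HGTConstraint",
    "FilterResult",
    "evaluate_constraint",
    "filter_trace",
    "read_constraint_file",
    "write_constraint_file",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HGTConstraint:
    """Strict ordering requirement: age(donor node) > age(recipient node)."""

    name: str
    donor: CladeDefinition
    recipient: CladeDefinition

    def __post_init__(self):
        if self.donor.leaves == self.recipient.leaves and self.donor.selector == self.recipient.selector:
            raise InvalidConstraintError(
                f"constraint {self.name!r}: donor and recipient resolve to the same node"
            )


@dataclass(frozen=True)
class FilterResult:
    """Outcome of conditional post-sampling one trace."""

    accepted_indices: tuple[int, ...]
    n_scanned: int
    acceptance_rate: float
    per_constraint_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        idx = self.accepted_indices
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("accepted indices must be strictly increasing")
        expected = len(idx) / self.n_scanned if self.n_scanned else 0.0
        if abs(self.acceptance_rate - expected) > 1e-12:
            raise ValueError("acceptance rate inconsistent with index count")


def evaluate_constraint(chronogram: Chronogram, constraint: HGTConstraint) -> bool:
    """True iff the donor node is strictly older than the recipient node.

    Exact age equality is degenerate for continuous node ages and counts as
    unsatisfied.
    """
    try:
        donor_age = resolve_node(chronogram, constraint.donor).age
        recipient_age = resolve_node(chronogram, constraint.recipient).age
    except HgtClockError as exc:
        raise type(exc)(f"constraint {constraint.name!r}: {exc}") from exc
    return donor_age > recipient_age


def filter_trace(
    trace: ChronogramTrace,
    constraints: Sequence[HGTConstraint],
    *,
    require_burn_in: bool = True,
) -> tuple[FilterResult, ChronogramTrace]:
    """Conditionally post-sample a trace: keep samples satisfying ALL constraints.

    Sample order is preserved; the acceptance rate is relative to the scanned
    (post-burn-in) sample count.  Zero accepted samples is reported with a
    prominent warning, not an error, so multi-model sweeps can continue.
    Constraints referencing unknown leaves fail on the first sample, before
    any partial result is produced.
    """
    if require_burn_in and not trace.burn_in_applied:
        warnings.warn(
            "filtering a trace without burn-in applied; pass require_burn_in=False "
            "to silence, or apply_burn_in() first",
            stacklevel=2,
        )
    # fail fast on unresolvable clade references
    if len(trace) and constraints:
        first = trace.samples[0]
        for constraint in constraints:
            evaluate_constraint(first, constraint)

    counts = {c.name: 0 for c in constraints}
    accepted: list[int] = []
    for i, sample in enumerate(trace):
        ok = True
        for constraint in constraints:
            if evaluate_constraint(sample, constraint):
                counts[constraint.name] += 1
            else:
                ok = False
        if ok:
            accepted.append(i)
    rate = len(accepted) / len(trace) if len(trace) else 0.0
    result = FilterResult(
        accepted_indices=tuple(accepted),
        n_scanned=len(trace),
        acceptance_rate=rate,
        per_constraint_counts=counts,
    )
    if constraints and not accepted:
        warnings.warn(
            f"HGT filtering of {trace.source or 'trace'} accepted 0 of "
            f"{len(trace)} samples; constrained summaries are unavailable",
            stacklevel=2,
        )
    filtered = trace.subset(accepted, source_suffix="|hgt-filtered")
    return result, filtered


# -- constraint file I/O ---------------------------------------------------
# dialect: name<TAB>donor_clade<TAB>donor_selector<TAB>recipient_clade<TAB>recipient_selector


def read_constraint_file(
    stream, clade_definitions: Sequence[CladeDefinition]
) -> list[HGTConstraint]:
    """Read constraint TSV against a table of named clades."""
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = Path(stream).read_text() if "\n" not in str(stream) else str(stream)
    by_name = {c.name: c for c in clade_definitions}
    constraints = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise FormatError(
                f"constraint line {lineno}: expected 5 tab-separated fields, got {len(parts)}"
            )
        name, donor_name, donor_sel, recip_name, recip_sel = (p.strip() for p in parts)
        for clade_name in (donor_name, recip_name):
            if clade_name not in by_name:
                raise FormatError(
                    f"constraint line {lineno}: unknown clade {clade_name!r}"
                )
        constraints.append(
            HGTConstraint(
                name=name,
                donor=by_name[donor_name].with_selector(donor_sel),
                recipient=by_name[recip_name].with_selector(recip_sel),
            )
        )
    return constraints


def write_constraint_file(constraints: Sequence[HGTConstraint]) -> str:
    lines = [
        f"{c.name}\t{c.donor.name}\t{c.donor.selector}\t{c.recipient.name}\t{c.recipient.selector}"
        for c in constraints
    ]
    return "\n".join(lines) + "\n"
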