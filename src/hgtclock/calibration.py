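"""Hard node-age calibrations and root priors.

A calibration is a hard maximum and/or minimum age (Ma) attached to the crown
MRCA of a two-taxon pair (the two-leaf-label convention of dating-software
calibration files) or to a named clade.  The file dialect is: a first line
with the calibration count, then one line per calibration —

    taxonA  taxonB  <upper>  <lower>

where *upper* is the maximum age and *lower* the minimum age, and ``-1`` is a
sentinel for "no bound" (fossil minima thus print upper = -1).

Root priors come in three shapes: ``flat`` (hard bounds, older > younger),
``gamma`` (mean/SD parameterized; keeps ages positive), or ``normal``
(mean/SD).  Only the flat shape generates hard violations in sample audits;
the distributional shapes parameterize the prior sampler.

This module also performs the mechanical prerequisite check for an "index
HGT": a transfer usable as a relative time constraint needs (i) a resolved
donor placement, (ii) donor/recipient clade phylogenies congruent with the
species tree, and (iii) an absolute calibration on the donor or (ideally) the
recipient crown group.  Only (iii) can be checked from calibration tables;
(i) and (ii) are gene-tree properties and are surfaced as notices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

from .chronotree import Chronogram, CladeDefinition
from .errors import FormatError, InvalidConstraintError

if TYPE_CHECKING:  # pragma: no cover
    from .hgt_filter import HGTConstraint

__all__ = [
    "Calibration",
    "RootPrior",
    "CalibrationViolation",
    "IndexHgtNotice",
    "read_calibration_file",
    "write_calibration_file",
    "check_sample",
    "check_index_hgt",
    "read_clade_definitions",
]

_NO_BOUND = -1.0


@dataclass(frozen=True)
class Calibration:
    """A hard age window on the crown MRCA of a taxon pair or clade."""

    label: str
    taxa: tuple[str, str] | None = None
    clade: CladeDefinition | None = None
    max_age: float | None = None  # upper limit, Ma; None = unbounded
    min_age: float | None = None  # lower limit, Ma; None = unbounded

    def __post_init__(self):
        if (self.taxa is None) == (self.clade is None):
            raise ValueError("exactly one of taxa or clade must be given")
        if (
            self.max_age is not None
            and self.min_age is not None
            and self.max_age < self.min_age
        ):
            raise FormatError(
                f"calibration {self.label!r}: maximum age {self.max_age} Ma is "
                f"younger than minimum age {self.min_age} Ma"
            )

    def leaves(self) -> frozenset[str]:
        return frozenset(self.taxa) if self.taxa else self.clade.leaves

    def resolve_age(self, chronogram: Chronogram) -> float:
        """Age of the calibrated node (crown MRCA) in one sample."""
        return chronogram.mrca(self.leaves()).age


@dataclass(frozen=True)
class RootPrior:
    """Prior on the root age: flat hard bounds or a mean/SD distribution."""

    shape: str  # "flat" | "gamma" | "normal"
    older: float | None = None  # flat upper bound, Ma
    younger: float | None = None  # flat lower bound, Ma
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self):
        if self.shape == "flat":
            if self.older is None or self.younger is None or self.older <= self.younger:
                raise ValueError("flat root prior requires older > younger bounds")
        elif self.shape in ("gamma", "normal"):
            if not (self.mean and self.mean > 0 and self.sd and self.sd > 0):
                raise ValueError(f"{self.shape} root prior requires mean > 0 and SD > 0")
        else:
            raise ValueError(f"unknown root prior shape {self.shape!r}")

    @classmethod
    def flat(cls, older: float, younger: float) -> "RootPrior":
        return cls(shape="flat", older=older, younger=younger)

    @classmethod
    def gamma(cls, mean: float, sd: float) -> "RootPrior":
        return cls(shape="gamma", mean=mean, sd=sd)

    @classmethod
    def normal(cls, mean: float, sd: float) -> "RootPrior":
        return cls(shape="normal", mean=mean, sd=sd)

    @classmethod
    def from_string(cls, text: str) -> "RootPrior":
        """Parse ``gamma:3900:200``, ``normal:2500:200`` or ``flat:3800:2450``."""
        parts = text.split(":")
        if len(parts) != 3:
            raise FormatError(f"cannot parse root prior {text!r}")
        shape, a, b = parts[0].lower(), float(parts[1]), float(parts[2])
        if shape == "flat":
            return cls.flat(older=max(a, b), younger=min(a, b))
        if shape in ("gamma", "normal"):
            return cls(shape=shape, mean=a, sd=b)
        raise FormatError(f"unknown root prior shape {shape!r}")


@dataclass(frozen=True)
class CalibrationViolation:
    label: str
    observed_age: float
    bound: float
    kind: str  # "max" (too old) | "min" (too young) | "root"

    def __str__(self) -> str:
        rel = "exceeds maximum" if self.kind == "max" else (
            "falls below minimum" if self.kind == "min" else "outside flat root bounds"
        )
        return f"{self.label}: age {self.observed_age:g} Ma {rel} {self.bound:g} Ma"


@dataclass(frozen=True)
class IndexHgtNotice:
    level: str  # "warning" | "info" | "notice"
    message: str


# -- file I/O --------------------------------------------------------------


def read_calibration_file(stream) -> list[Calibration]:
    """Parse the count-headed ``taxonA taxonB upper lower`` dialect."""
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        from pathlib import Path

        text = Path(stream).read_text() if "\n" not in str(stream) else str(stream)
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty calibration file")
    try:
        count = int(lines[0])
    except ValueError as exc:
        raise FormatError(f"first line must be the calibration count, got {lines[0]!r}") from exc
    body = lines[1:]
    if len(body) != count:
        raise FormatError(f"header declares {count} calibrations, file has {len(body)}")
    calibrations = []
    for i, line in enumerate(body, start=1):
        tokens = line.split()
        if len(tokens) < 4:
            raise FormatError(f"calibration line {i}: expected 'taxonA taxonB upper lower'")
        *label_tokens, taxon_a, taxon_b, upper_s, lower_s = tokens
        try:
            upper, lower = float(upper_s), float(lower_s)
        except ValueError as exc:
            raise FormatError(f"calibration line {i}: non-numeric limit in {line!r}") from exc
        calibrations.append(
            Calibration(
                label=" ".join(label_tokens) if label_tokens else f"cal{i}",
                taxa=(taxon_a, taxon_b),
                max_age=None if upper == _NO_BOUND else upper,
                min_age=None if lower == _NO_BOUND else lower,
            )
        )
    return calibrations


def write_calibration_file(calibrations: Sequence[Calibration]) -> str:
    """Serialize back to the count-headed dialect (-1 sentinel for no bound)."""
    lines = [str(len(calibrations))]
    for cal in calibrations:
        if cal.taxa is None:
            raise FormatError(
                f"calibration {cal.label!r} is clade-based and has no two-taxon form"
            )
        upper = _NO_BOUND if cal.max_age is None else cal.max_age
        lower = _NO_BOUND if cal.min_age is None else cal.min_age
        lines.append(f"{cal.taxa[0]} {cal.taxa[1]} {upper:g} {lower:g}")
    return "\n".join(lines) + "\n"


def read_clade_definitions(stream) -> list[CladeDefinition]:
    """Read clade TSV: name<TAB>crown|stem<TAB>comma-separated leaf labels."""
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        from pathlib import Path

        text = Path(stream).read_text() if "\n" not in str(stream) else str(stream)
    clades = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(
                f"clade line {lineno}: expected name<TAB>selector<TAB>leaves, got {line!r}"
            )
        name, selector, leaves = parts
        clades.append(
            CladeDefinition(
                name=name,
                leaves=frozenset(l.strip() for l in leaves.split(",") if l.strip()),
                selector=selector.strip(),
            )
        )
    return clades


# -- sample auditing -------------------------------------------------------


def check_sample(
    chronogram: Chronogram,
    calibrations: Iterable[Calibration],
    root_prior: RootPrior | None = None,
) -> list[CalibrationViolation]:
    """Audit one posterior sample against hard calibration bounds.

    A flat root prior contributes hard bounds on the root age; gamma/normal
    root priors are distributions, not bounds, and never generate violations.
    """
    violations: list[CalibrationViolation] = []
    for cal in calibrations:
        age = cal.resolve_age(chronogram)
        if cal.max_age is not None and age > cal.max_age:
            violations.append(CalibrationViolation(cal.label, age, cal.max_age, "max"))
        if cal.min_age is not None and age < cal.min_age:
            violations.append(CalibrationViolation(cal.label, age, cal.min_age, "min"))
    if root_prior is not None and root_prior.shape == "flat":
        root_age = chronogram.root_age
        if not (root_prior.younger <= root_age <= root_prior.older):
            bound = root_prior.older if root_age > root_prior.older else root_prior.younger
            violations.append(CalibrationViolation("root", root_age, bound, "root"))
    return violations


# -- index-HGT prerequisite check -----------------------------------------


def check_index_hgt(
    constraint: "HGTConstraint",
    calibrations: Iterable[Calibration],
    clade_definitions: Sequence[CladeDefinition] | None = None,
) -> list[IndexHgtNotice]:
    """Check the calibration prerequisite of an index HGT.

    Warns when neither the donor nor recipient crown clade contains a
    calibrated node (the transfer then propagates no absolute dates), and
    informs when only the donor side is calibrated (a recipient-side
    calibration is preferable because the constraint acts on the recipient's
    crown).  Gene-tree prerequisites — resolved donor placement and
    species-tree congruence — cannot be evaluated from calibration tables and
    are emitted as unconditional notices.
    """
    donor, recipient = constraint.donor, constraint.recipient
    if donor.leaves == recipient.leaves:
        raise InvalidConstraintError(
            f"constraint {constraint.name!r}: donor and recipient clades are identical"
        )
    notices = [
        IndexHgtNotice(
            "notice",
            "prerequisite (gene-tree support): the transfer topology must be "
            "resolved with a well-supported branch inside the donor clade — "
            "not evaluated here",
        ),
        IndexHgtNotice(
            "notice",
            "prerequisite (congruence): donor and recipient clade phylogenies "
            "must match their species-tree counterparts — not evaluated here",
        ),
    ]

    def calibrated(clade: CladeDefinition) -> bool:
        return any(cal.leaves() <= clade.leaves for cal in calibrations)

    donor_cal = calibrated(donor)
    recipient_cal = calibrated(recipient)
    if not donor_cal and not recipient_cal:
        notices.append(
            IndexHgtNotice(
                "warning",
                f"constraint {constraint.name!r}: neither donor nor recipient "
                "crown contains a calibrated node; the HGT propagates no "
                "absolute dates",
            )
        )
    elif donor_cal and not recipient_cal:
        notices.append(
            IndexHgtNotice(
                "info",
                f"constraint {constraint.name!r}: only the donor side is "
                "calibrated; a recipient-side calibration is preferable",
            )
        )
    return notices
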