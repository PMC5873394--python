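"""Dated trees, posterior trace parsing, and clade-to-node resolution.

The unit record here is the chronogram: a rooted tree whose branch lengths are
durations in Ma (millions of years before present), so that every node carries
an age equal to its path-length to any descendant leaf.  Dating software emits
posterior samples of such trees as a "datedist" file — one newick string per
line, optionally preceded by a non-tree header line.  This module parses those
streams into :class:`ChronogramTrace` objects, validates the ultrametric
structure, and maps named clades (crown or stem) onto nodes of each sample.

Conventions: ages are in Ma before present, larger is older; extant tips sit
at age 0; an internal node must be strictly older than each of its children.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np

from .errors import (
    AnnotationMismatchError,
    EmptyTraceError,
    LeafSetMismatchError,
    NoStemNodeError,
    NotMonophyleticError,
    TraceParseError,
    UltrametricityError,
    UnknownTaxonError,
)

__all__ = [
    "Chronogram",
    "ChronogramTrace",
    "CladeDefinition",
    "AgeTrace",
    "UltrametricViolation",
    "parse_trace",
    "validate_ultrametric",
    "resolve_node",
    "clade_age_trace",
    "write_annotated_tree",
]

#: default relative tolerance for agreement of root-to-leaf path sums
DEFAULT_REL_TOL = 1e-6
#: absolute tolerance (Ma) below which a parent-child age difference is a tie
DEFAULT_TIE_TOL = 1e-9


@dataclass(frozen=True)
class CladeDefinition:
    """A named clade: a leaf-label set plus a crown/stem selector.

    ``crown`` selects the MRCA of the leaf set (the crown-group node);
    ``stem`` selects the parent of that MRCA, i.e. the divergence of the
    clade from its sister lineage.
    """

    name: str
    leaves: frozenset[str]
    selector: str = "crown"

    def __post_init__(self):
        if self.selector not in ("crown", "stem"):
            raise ValueError(f"selector must be 'crown' or 'stem', got {self.selector!r}")
        if not self.leaves:
            raise ValueError(f"clade {self.name!r} has an empty leaf set")
        object.__setattr__(self, "leaves", frozenset(self.leaves))

    def with_selector(self, selector: str) -> "CladeDefinition":
        return CladeDefinition(self.name, self.leaves, selector)


@dataclass(frozen=True)
class AgeTrace:
    """Ordered per-sample ages (Ma) for one named node."""

    name: str
    ages: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        if self.ages.ndim != 1:
            raise ValueError("ages must be one-dimensional")
        if len(self.ages) and self.ages.min() < 0:
            raise ValueError(f"negative age in trace for {self.name!r}")

    def __len__(self) -> int:
        return len(self.ages)


@dataclass(frozen=True)
class UltrametricViolation:
    leaf: str
    expected_depth: float
    observed_depth: float


class Chronogram:
    """A rooted, dated tree: topology plus a node age for every node.

    Wraps a :class:`dendropy.Tree`; each node gets an ``age`` attribute equal
    to its branch-length path sum to any descendant leaf.  Construction
    validates ultrametricity (all path sums to leaves agree within a relative
    tolerance) and strict parent-older-than-child ordering.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        *,
        ultrametricity: str = "reject",
        rel_tol: float = DEFAULT_REL_TOL,
        tie_tol: float = DEFAULT_TIE_TOL,
    ):
        if ultrametricity not in ("reject", "repair", "defer"):
            raise ValueError("ultrametricity must be 'reject', 'repair' or 'defer'")
        self.tree = tree
        self._compute_ages(ultrametricity, rel_tol)
        if ultrametricity != "defer":
            self._check_ordering(tie_tol)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, **kwargs) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several unrelated types
            raise TraceParseError(str(exc)) from exc
        return cls(tree, **kwargs)

    def _compute_ages(self, mode: str, rel_tol: float) -> None:
        # postorder: each node accumulates all leaf path sums below it
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node._leaf_depths = [0.0]
                node.age = 0.0
                continue
            depths: list[float] = []
            for child in node.child_nodes():
                length = child.edge.length if child.edge.length is not None else 0.0
                depths.extend(d + length for d in child._leaf_depths)
            node._leaf_depths = depths
            scale = max(abs(max(depths)), 1.0)
            spread = max(depths) - min(depths)
            if spread > rel_tol * scale and mode == "reject":
                raise UltrametricityError(
                    f"node path sums to leaves disagree (spread {spread:g} Ma); "
                    "re-parse with ultrametricity='repair' to average them"
                )
            node.age = float(np.mean(depths)) if mode == "repair" else depths[0]
        for node in self.tree.postorder_node_iter():
            del node._leaf_depths

    def _check_ordering(self, tie_tol: float) -> None:
        for node in self.tree.preorder_node_iter():
            for child in node.child_nodes():
                if node.age - child.age <= tie_tol:
                    raise TraceParseError(
                        f"node age {node.age:g} does not strictly exceed child age "
                        f"{child.age:g} (tie tolerance {tie_tol:g} Ma)"
                    )

    # -- basic queries -----------------------------------------------------

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    @property
    def root_age(self) -> float:
        return self.root.age

    def node_leaves(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def mrca(self, leaves: Iterable[str]) -> dendropy.Node:
        wanted = set(leaves)
        missing = wanted - self.leaf_labels
        if missing:
            raise UnknownTaxonError(
                f"leaf label(s) absent from tree: {', '.join(sorted(missing))}"
            )
        if len(wanted) == 1:
            (label,) = wanted
            for lf in self.tree.leaf_node_iter():
                if lf.taxon.label == label:
                    return lf
        node = self.tree.mrca(taxon_labels=list(wanted))
        if node is None:  # pragma: no cover - dendropy returns root otherwise
            raise UnknownTaxonError(f"could not resolve MRCA of {sorted(wanted)}")
        return node

    def as_newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick",
                unquoted_underscores=True,
                suppress_rooting=True,
            ).strip()
        )


@dataclass
class ChronogramTrace:
    """An ordered collection of chronograms from one dating run.

    ``n_saved`` records the number of saved points *before* burn-in so the
    burn-in rule (drop the first ``floor(fraction * N)``) stays well defined
    even after trimming.
    """

    samples: list[Chronogram]
    n_saved: int
    source: str = ""
    burn_in_applied: bool = False
    burn_in_fraction: float = 0.0

    def __post_init__(self):
        if self.n_saved < 1:
            raise EmptyTraceError(f"trace {self.source!r} holds no samples")
        leafsets = {c.leaf_labels for c in self.samples}
        if len(leafsets) > 1:
            raise LeafSetMismatchError(
                f"samples in {self.source!r} carry {len(leafsets)} distinct leaf sets"
            )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[Chronogram]:
        return iter(self.samples)

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self.samples[0].leaf_labels

    def subset(self, indices: Sequence[int], source_suffix: str = "") -> "ChronogramTrace":
        return replace(
            self,
            samples=[self.samples[i] for i in indices],
            source=self.source + source_suffix,
        )

    def as_datedist(self) -> str:
        """Serialize as a datedist stream: one newick per line."""
        return "".join(c.as_newick() + "\n" for c in self.samples)


# -- parsing ---------------------------------------------------------------


def _iter_lines(stream) -> Iterator[str]:
    if isinstance(stream, Path):
        with open(stream, "r") as fh:
            yield from fh
    elif isinstance(stream, str):
        looks_like_content = (
            "\n" in stream or stream.lstrip().startswith("(") or stream.strip().endswith(";")
        )
        if looks_like_content:
            yield from io.StringIO(stream)
        else:
            with open(stream, "r") as fh:
                yield from fh
    else:
        yield from stream


def parse_trace(
    stream,
    *,
    source: str = "",
    ultrametricity: str = "reject",
    rel_tol: float = DEFAULT_REL_TOL,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> ChronogramTrace:
    """Parse a datedist stream (one newick per line) into a trace.

    A leading non-tree header line (e.g. a sample count, as some dating
    programs emit) is tolerated and skipped.  ``ultrametricity`` is either
    ``"reject"`` (raise on disagreeing path sums) or ``"repair"`` (assign each
    node the mean of its leaf path sums).

    Raises :class:`EmptyTraceError` for a stream with no tree lines,
    :class:`TraceParseError` (with line number) for malformed newick, and
    :class:`LeafSetMismatchError` when samples disagree on their leaf set.
    """
    samples: list[Chronogram] = []
    first_content_line = True
    for lineno, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.strip()
        if not line:
            continue
        looks_like_tree = line.startswith("(") and line.endswith(";")
        if first_content_line and not looks_like_tree:
            first_content_line = False  # header line: tolerated, skipped
            continue
        first_content_line = False
        try:
            chrono = Chronogram.from_newick(
                line, ultrametricity=ultrametricity, rel_tol=rel_tol, tie_tol=tie_tol
            )
        except TraceParseError as exc:
            raise TraceParseError(str(exc), line_number=lineno) from exc
        except UltrametricityError as exc:
            raise UltrametricityError(f"line {lineno}: {exc}") from exc
        samples.append(chrono)
    if not samples:
        raise EmptyTraceError(f"no tree lines found in {source or 'stream'}")
    return ChronogramTrace(samples=samples, n_saved=len(samples), source=source)


def validate_ultrametric(
    chronogram: Chronogram, rel_tol: float = DEFAULT_REL_TOL
) -> list[UltrametricViolation]:
    """Report leaves whose root-to-leaf path sum deviates from the consensus.

    The consensus depth is the median root-to-leaf path sum, which pins the
    expectation to the unperturbed majority when a single branch is off.
    Returns an empty list iff all path sums agree within ``rel_tol``.
    """
    depths: dict[str, float] = {}

    def walk(node: dendropy.Node, depth: float) -> None:
        if node.is_leaf():
            depths[node.taxon.label] = depth
            return
        for child in node.child_nodes():
            length = child.edge.length if child.edge.length is not None else 0.0
            walk(child, depth + length)

    walk(chronogram.root, 0.0)
    expected = float(np.median(list(depths.values())))
    scale = max(abs(expected), 1.0)
    return [
        UltrametricViolation(leaf=leaf, expected_depth=expected, observed_depth=obs)
        for leaf, obs in sorted(depths.items())
        if abs(obs - expected) > rel_tol * scale
    ]


# -- clade resolution ------------------------------------------------------


def resolve_node(
    chronogram: Chronogram, clade: CladeDefinition, *, strict: bool = True
) -> dendropy.Node:
    """Resolve a clade definition to a node of one sample.

    Crown selects the MRCA of the clade's leaves; stem selects that MRCA's
    parent.  In strict mode (default) a non-monophyletic leaf set raises
    :class:`NotMonophyleticError`; with ``strict=False`` the MRCA is returned
    regardless (it then spans extra leaves).
    """
    mrca = chronogram.mrca(clade.leaves)
    if strict and chronogram.node_leaves(mrca) != clade.leaves:
        extra = sorted(chronogram.node_leaves(mrca) - clade.leaves)
        raise NotMonophyleticError(
            f"clade {clade.name!r} is not monophyletic in this sample; "
            f"MRCA additionally spans: {', '.join(extra[:5])}"
            + ("..." if len(extra) > 5 else "")
        )
    if clade.selector == "stem":
        if mrca.parent_node is None:
            raise NoStemNodeError(
                f"clade {clade.name!r}: MRCA is the root, no stem node exists"
            )
        return mrca.parent_node
    return mrca


def clade_age_trace(
    trace: ChronogramTrace, clade: CladeDefinition, *, strict: bool = True
) -> AgeTrace:
    """Extract the per-sample age of one clade's node across a trace."""
    if len(trace) == 0:
        raise EmptyTraceError("cannot extract ages from an empty trace")
    ages = np.empty(len(trace), dtype=float)
    for i, sample in enumerate(trace):
        try:
            ages[i] = resolve_node(sample, clade, strict=strict).age
        except Exception as exc:
            raise type(exc)(f"sample {i}: {exc}") from exc
    return AgeTrace(name=f"{clade.selector} {clade.name}", ages=ages)


# -- annotated output ------------------------------------------------------


def write_annotated_tree(
    chronogram: Chronogram,
    rows: Mapping[str, tuple],
    clade_definitions: Sequence[CladeDefinition],
    dialect: str = "newick",
) -> str:
    """Render summary ages onto a topology.

    ``rows`` maps clade names to ``(median, hpd_lower, hpd_upper)`` tuples
    (the HPD bounds may be None).  Every internal node of the topology must be
    covered by exactly one resolved clade row; leaves sit at age 0.  The
    ``newick`` dialect writes branch lengths recomputed from the median ages
    (so path sums reproduce them); the ``nexus`` dialect adds
    FigTree-compatible bracketed comments carrying median and HPD bounds.
    """
    if dialect not in ("newick", "nexus"):
        raise ValueError(f"unknown dialect {dialect!r}")
    by_name = {c.name: c for c in clade_definitions}
    node_values: dict[int, tuple] = {}
    for name, values in rows.items():
        if name not in by_name:
            raise AnnotationMismatchError(f"row {name!r} matches no clade definition")
        node = resolve_node(chronogram, by_name[name])
        node_values[id(node)] = values
    internal = [n for n in chronogram.tree.preorder_node_iter() if not n.is_leaf()]
    uncovered = [n for n in internal if id(n) not in node_values]
    if uncovered:
        raise AnnotationMismatchError(
            f"{len(uncovered)} internal node(s) carry no summary row"
        )

    def age_of(node: dendropy.Node) -> float:
        return 0.0 if node.is_leaf() else float(node_values[id(node)][0])

    def comment(node: dendropy.Node) -> str:
        if dialect != "nexus" or node.is_leaf():
            return ""
        median, lo, hi = node_values[id(node)][:3]
        if lo is None or hi is None:
            return f"[&median={median:.6g}]"
        return f"[&median={median:.6g},hpd={{{lo:.6g},{hi:.6g}}}]"

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            core = node.taxon.label
        else:
            core = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
        parent = node.parent_node
        if parent is None:
            return core + comment(node)
        length = age_of(parent) - age_of(node)
        if length < 0:
            raise AnnotationMismatchError(
                "median ages violate parent-older-than-child ordering"
            )
        return f"{core}{comment(node)}:{length:.10g}"

    newick = render(chronogram.root) + ";"
    if dialect == "newick":
        return newick + "\n"
    taxa = sorted(chronogram.leaf_labels)
    lines = [
        "#NEXUS",
        "begin taxa;",
        f"\tdimensions ntax={len(taxa)};",
        "\ttaxlabels",
        *[f"\t\t{t}" for t in taxa],
        "\t;",
        "end;",
        "begin trees;",
        f"\ttree summary = [&R] {newick}",
        "end;",
    ]
    return "\n".join(lines) + "\n"
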