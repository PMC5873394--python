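"""Synthetic chronogram traces: calibrated-prior sampling and jittered
pseudo-posteriors.

Two generators cover the two ways this toolkit consumes dated-tree traces:

* :func:`sample_prior` runs a small MCMC over node ages on a fixed rooted
  topology whose stationary density is the calibrated prior a dating program
  would sample "under the prior": the root age follows a gamma (mean/SD
  parameterized, keeping ages positive), normal, or flat prior; conditional on
  the root, uncalibrated internal-node ages are uniform subject to the
  parent-older-than-child ordering; hard calibration bounds enter as
  indicator functions.  Non-root nodes admit an exact conditional update
  (uniform on the interval their neighbours and bounds leave open), so only
  the root needs a Metropolis random walk.

* :func:`simulate_posterior_trace` jitters a known true chronogram with
  truncated normal noise, sample by sample, recording the exact per-sample
  ages in a truth ledger so downstream operations (clade age extraction,
  filtering rates, summary recovery) can be checked against bookkeeping that
  never touches the tree-parsing path.

Both are deterministic given their seeds.  Neither models sequence evolution
or branch rates — traces carry node ages only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .calibration import Calibration, RootPrior
from .chronotree import AgeTrace, Chronogram, ChronogramTrace
from .errors import InfeasibleSpecError

__all__ = [
    "PriorSpec",
    "JitterSpec",
    "yule_topology",
    "sample_prior",
    "simulate_posterior_trace",
    "paired_age_generator",
    "node_keys",
]


# -- topology helpers ------------------------------------------------------


def yule_topology(n_leaves: int, seed: int) -> dendropy.Tree:
    """Random rooted binary topology by sequential random cherry attachment.

    Starts from a two-leaf cherry and repeatedly replaces a uniformly chosen
    leaf with a cherry of (that leaf, next new leaf).  Leaf labels are
    ``t1..tn``; no branch lengths are assigned.  Reproducible by seed.
    """
    if n_leaves < 2:
        raise ValueError(f"need at least 2 leaves, got {n_leaves}")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    def new_leaf(i: int) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label=f"t{i}")
        return node

    leaves = [new_leaf(1), new_leaf(2)]
    tree.seed_node.add_child(leaves[0])
    tree.seed_node.add_child(leaves[1])
    for i in range(3, n_leaves + 1):
        target = leaves[int(rng.integers(len(leaves)))]
        parent = target.parent_node
        joint = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(joint)
        joint.add_child(target)
        fresh = new_leaf(i)
        joint.add_child(fresh)
        leaves.append(fresh)
    tree.is_rooted = True
    return tree


def node_keys(tree: dendropy.Tree) -> list[str]:
    """Stable names for a topology's nodes, in preorder.

    Leaves keep their labels; an unlabeled internal node is named
    ``anc_<smallest descendant-leaf label>_<descendant leaf count>``, which is
    unique: two clades sharing their smallest leaf are nested, and nested
    clades of equal size are identical.
    """
    keys = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            keys.append(node.taxon.label)
        elif node.label:
            keys.append(node.label)
        else:
            leaves = [lf.taxon.label for lf in node.leaf_iter()]
            keys.append(f"anc_{min(leaves)}_{len(leaves)}")
    return keys


def _chronogram_from_ages(
    template: dendropy.Tree, ages: np.ndarray, order: list[dendropy.Node]
) -> Chronogram:
    """Build a fresh chronogram for the template topology and given node ages.

    ``order`` is the template's preorder node list; ``ages`` is aligned to it.
    The taxon namespace is shared across samples (labels are immutable here).
    """
    index = {id(n): i for i, n in enumerate(order)}
    tree = dendropy.Tree(taxon_namespace=template.taxon_namespace)

    def copy(src: dendropy.Node, dst: dendropy.Node) -> None:
        for child in src.child_nodes():
            node = dendropy.Node()
            node.taxon = child.taxon
            node.edge.length = float(
                ages[index[id(child.parent_node)]] - ages[index[id(child)]]
            )
            dst.add_child(node)
            copy(child, node)

    copy(template.seed_node, tree.seed_node)
    tree.is_rooted = True
    return Chronogram(tree)


# -- calibrated prior sampling --------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Inputs for sampling node ages under a calibrated prior.

    ``n_samples`` is the number of emitted chronograms; the sampler runs
    ``ceil(n_samples * thin / 0.9)`` sweeps so that 10% warm-up sweeps can be
    discarded before thinned emission.  The seed is mandatory and recorded on
    the output trace's source label.
    """

    topology: dendropy.Tree
    root_prior: RootPrior
    calibrations: tuple[Calibration, ...] = ()
    n_samples: int = 1000
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.thin < 1:
            raise ValueError("n_samples and thin must be positive")
        object.__setattr__(self, "calibrations", tuple(self.calibrations))

    @property
    def iterations(self) -> int:
        return math.ceil(self.n_samples * self.thin / 0.9) + 1


def _propagate_bounds(
    order: list[dendropy.Node],
    cal_min: np.ndarray,
    cal_max: np.ndarray,
    root_prior: RootPrior,
) -> tuple[np.ndarray, np.ndarray]:
    """Interval propagation of hard bounds; raises on infeasibility."""
    n = len(order)
    index = {id(node): i for i, node in enumerate(order)}
    lower = cal_min.copy()
    upper = cal_max.copy()
    if root_prior.shape == "flat":
        lower[0] = max(lower[0], root_prior.younger)
        upper[0] = min(upper[0], root_prior.older)
    # upward: a node is at least as old as every descendant's minimum
    for node in reversed(order):  # reverse preorder = children before parents
        i = index[id(node)]
        if node.is_leaf():
            lower[i] = max(lower[i], 0.0)
            upper[i] = 0.0
            continue
        for child in node.child_nodes():
            lower[i] = max(lower[i], lower[index[id(child)]])
    # downward: a node is at most as old as its parent's maximum
    for node in order:
        i = index[id(node)]
        if node.parent_node is not None and not node.is_leaf():
            upper[i] = min(upper[i], upper[index[id(node.parent_node)]])
        if lower[i] > upper[i]:
            raise InfeasibleSpecError(
                f"bounds infeasible at node {i}: minimum {lower[i]:g} Ma exceeds "
                f"maximum {upper[i]:g} Ma"
            )
    return lower, upper


def sample_prior(spec: PriorSpec) -> ChronogramTrace:
    """MCMC sample of node ages under the calibrated prior (see module docs).

    Sweeps update internal nodes in random order.  Non-root nodes draw
    uniformly on the exact conditional interval (between the oldest child /
    minimum bound and the parent / maximum bound).  The root uses a Gaussian
    random-walk proposal accepted against the root prior density times the
    ordering and bound indicators; under a flat prior the root conditional is
    itself uniform and is drawn exactly.

    Raises :class:`InfeasibleSpecError` before sampling if interval
    propagation finds contradictory bounds.
    """
    rng = np.random.default_rng(spec.seed)
    template = spec.topology
    order = list(template.preorder_node_iter())
    index = {id(node): i for i, node in enumerate(order)}
    n = len(order)

    cal_min = np.zeros(n)
    cal_max = np.full(n, np.inf)
    for cal in spec.calibrations:
        leaves = cal.leaves()
        labels = {lf.taxon.label for lf in template.leaf_node_iter()}
        missing = leaves - labels
        if missing:
            raise InfeasibleSpecError(
                f"calibration {cal.label!r} references unknown taxa: {sorted(missing)}"
            )
        node = template.mrca(taxon_labels=list(leaves))
        i = index[id(node)]
        if cal.min_age is not None:
            cal_min[i] = max(cal_min[i], cal.min_age)
        if cal.max_age is not None:
            cal_max[i] = min(cal_max[i], cal.max_age)

    lower, upper = _propagate_bounds(order, cal_min, cal_max, spec.root_prior)

    internal = [i for i, node in enumerate(order) if not node.is_leaf()]
    children = {
        i: [index[id(c)] for c in order[i].child_nodes()] for i in internal
    }
    parent = {
        i: (index[id(order[i].parent_node)] if order[i].parent_node else None)
        for i in internal
    }

    # feasible initialization: root strictly above its lower envelope, then
    # each child at the midpoint of its open interval
    ages = np.zeros(n)
    rp = spec.root_prior
    if rp.shape == "flat":
        ages[0] = 0.5 * (lower[0] + upper[0])
    else:
        ages[0] = min(max(rp.mean, lower[0] + 1.0), upper[0])
    for i in internal:
        if i == 0:
            continue
        hi = min(ages[parent[i]], upper[i])
        ages[i] = 0.5 * (lower[i] + hi)

    if rp.shape == "gamma":
        shape_par = rp.mean**2 / rp.sd**2
        scale_par = rp.sd**2 / rp.mean
        root_logpdf = lambda x: stats.gamma.logpdf(x, a=shape_par, scale=scale_par)
        step = rp.sd
    elif rp.shape == "normal":
        root_logpdf = lambda x: stats.norm.logpdf(x, loc=rp.mean, scale=rp.sd)
        step = rp.sd
    else:
        root_logpdf = None
        step = (rp.older - rp.younger) / 6.0

    sweeps = spec.iterations
    warmup = math.floor(0.1 * sweeps)
    samples: list[Chronogram] = []
    emitted_since = 0
    for sweep in range(sweeps):
        for i in rng.permutation(internal):
            kids = max(ages[j] for j in children[i])
            if i == 0:  # root
                lo = max(kids, lower[0])
                hi = upper[0]
                if root_logpdf is None:
                    ages[0] = rng.uniform(lo, hi)
                else:
                    proposal = ages[0] + step * rng.standard_normal()
                    if proposal > lo and proposal <= hi:
                        log_ratio = root_logpdf(proposal) - root_logpdf(ages[0])
                        if np.log(rng.uniform()) < log_ratio:
                            ages[0] = proposal
            else:
                lo = max(kids, lower[i])
                hi = min(ages[parent[i]], upper[i])
                ages[i] = rng.uniform(lo, hi)
        if sweep < warmup:
            continue
        if (sweep - warmup) % spec.thin == 0 and len(samples) < spec.n_samples:
            samples.append(_chronogram_from_ages(template, ages, order))
    return ChronogramTrace(
        samples=samples,
        n_saved=len(samples),
        source=f"prior-sample(seed={spec.seed})",
    )


# -- jittered pseudo-posterior --------------------------------------------


@dataclass(frozen=True)
class JitterSpec:
    """A true chronogram plus per-node jitter SD (Ma), sample count and seed."""

    truth: Chronogram
    sd: float | Mapping[str, float] = 10.0
    n_samples: int = 100
    seed: int = 0

    def __post_init__(self):
        sds = (
            self.sd.values() if isinstance(self.sd, Mapping) else [self.sd]
        )
        if any(s < 0 for s in sds):
            raise ValueError("jitter SD must be non-negative")
        if self.n_samples < 1:
            raise ValueError("sample count must be at least 1")


def simulate_posterior_trace(spec: JitterSpec) -> tuple[ChronogramTrace, pd.DataFrame]:
    """Pseudo-posterior trace around a true chronogram, plus its truth ledger.

    Node ages are redrawn root-down per sample from normals centered on the
    true ages and truncated to (0, parent age), so ordering and positivity
    hold in every sample by construction.  The returned ledger is a DataFrame
    with one row per sample and one column per node (named per
    :func:`node_keys`); its ``attrs["true_ages"]`` carries the generating
    ages.  Leaves stay at age 0 and are omitted from the ledger.
    """
    template = spec.truth.tree
    order = list(template.preorder_node_iter())
    keys = node_keys(template)
    index = {id(node): i for i, node in enumerate(order)}
    true_ages = np.array([node.age for node in order])
    rng = np.random.default_rng(spec.seed)

    def sd_for(i: int) -> float:
        if isinstance(spec.sd, Mapping):
            return float(spec.sd.get(keys[i], 0.0))
        return float(spec.sd)

    internal = [i for i, node in enumerate(order) if not order[i].is_leaf()]
    matrix = np.zeros((spec.n_samples, len(order)))
    # preorder over nodes, vectorized over samples: each node's upper bound is
    # the already-drawn parent age of the same sample
    for i in internal:
        parent_node = order[i].parent_node
        hi = (
            matrix[:, index[id(parent_node)]]
            if parent_node is not None
            else np.full(spec.n_samples, np.inf)
        )
        sd = sd_for(i)
        if sd == 0.0:
            # truth conflicts with a jittered parent: pin just below the parent
            matrix[:, i] = np.minimum(true_ages[i], hi * (1.0 - 1e-9))
            continue
        a = (0.0 - true_ages[i]) / sd
        b = (hi - true_ages[i]) / sd
        matrix[:, i] = stats.truncnorm.rvs(
            a, b, loc=true_ages[i], scale=sd, size=spec.n_samples, random_state=rng
        )

    samples = [
        _chronogram_from_ages(template, matrix[s], order)
        for s in range(spec.n_samples)
    ]
    trace = ChronogramTrace(
        samples=samples,
        n_saved=spec.n_samples,
        source=f"jitter(seed={spec.seed})",
    )
    ledger = pd.DataFrame(
        matrix[:, internal], columns=[keys[i] for i in internal]
    )
    ledger.attrs["true_ages"] = {keys[i]: float(true_ages[i]) for i in internal}
    return trace, ledger


# -- analytic paired draws -------------------------------------------------


def paired_age_generator(
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
    correlation: float,
    n: int,
    seed: int,
) -> tuple[AgeTrace, AgeTrace]:
    """Jointly Gaussian age pairs with given marginals and correlation.

    Used for analytic checks of ordering probabilities: for independent
    normals, P(A > B) = Phi((mean_a - mean_b) / sqrt(sd_a^2 + sd_b^2)).
    """
    if not -1.0 <= correlation <= 1.0:
        raise ValueError(f"correlation must be in [-1, 1], got {correlation}")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    a = mean_a + sd_a * z1
    b = mean_b + sd_b * (correlation * z1 + math.sqrt(1.0 - correlation**2) * z2)
    return AgeTrace("A", a), AgeTrace("B", b)
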