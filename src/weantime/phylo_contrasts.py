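"""Phylogenetically independent contrasts.

Comparative species data are not independent draws: close relatives
resemble each other.  Under a Brownian-motion model of trait change along
an ultrametric tree, Felsenstein's pruning turns T tip values into T - 1
standardized contrasts that are mutually independent with common variance.
At each internal node joining daughters with values x1, x2 on branches of
length v1, v2:

    contrast   = (x1 - x2) / sqrt(v1 + v2)
    node value = (x1/v1 + x2/v2) / (1/v1 + 1/v2)

and the node's own parent branch is lengthened by v1*v2/(v1 + v2) to
account for the uncertainty of the ancestral estimate.

Contrast sets from two traits on the same tree are correlated *through the
origin* (contrast signs are arbitrary), the standard convention; the
through-origin correlation is identical to the maximum-likelihood GLS
correlation under the Brownian covariance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats

from .errors import NewickParseError, PairingError, ValidationError

DEFAULT_POLYTOMY_EPSILON = 1e-8  # My; avoids zero division after polytomy resolution


class PhyloTree:
    """A rooted tree with branch lengths, thin wrapper over ``dendropy.Tree``."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.tree.is_rooted = True

    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path lengths."""
        depths: dict[str, float] = {}
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = np.array(list(self.tip_depths().values()))
        span = depths.max() - depths.min()
        return bool(span <= rel_tol * max(depths.max(), 1e-300))

    def scale_branches(self, factor: float) -> "PhyloTree":
        clone = self.tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        return PhyloTree(clone)

    def __repr__(self) -> str:
        return f"PhyloTree(n_tips={self.n_tips})"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Raises :class:`NewickParseError` (with the character position where the
    underlying parser reports one) on malformed input.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(f"missing terminal ';' at position {len(stripped)}")
    if stripped.count("(") != stripped.count(")"):
        raise NewickParseError(
            f"unbalanced parentheses: {stripped.count('(')} '(' vs {stripped.count(')')} ')'"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise NewickParseError("duplicate tip labels in Newick input")
    return PhyloTree(tree)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


# ----------------------------------------------------------------------
# Contrasts
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastSet:
    """Standardized contrasts in post-order, with their pre-standardization SDs.

    ``node_ids`` identify the internal nodes (stable within one tree
    traversal) so that two traits contrasted on the same tree can be paired.
    """

    node_ids: tuple[str, ...]
    contrasts: tuple[float, ...]
    expected_sd: tuple[float, ...]

    @property
    def n_contrasts(self) -> int:
        return len(self.contrasts)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.contrasts), np.asarray(self.expected_sd)

    def write(self, path, sep: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write(sep.join(["node", "contrast", "expected_sd"]) + "\n")
            for nid, c, s in zip(self.node_ids, self.contrasts, self.expected_sd):
                fh.write(sep.join([nid, repr(c), repr(s)]) + "\n")


def _prepare_tree(tree: PhyloTree, epsilon: float) -> dendropy.Tree:
    work = tree.tree.clone(depth=1)
    work.resolve_polytomies(rng=None)  # deterministic arbitrary resolution
    for edge in work.preorder_edge_iter():
        if edge.head_node is work.seed_node:
            continue
        if edge.length is None or edge.length == 0.0:
            if edge.head_node.is_leaf():
                if edge.length is None:
                    raise ValidationError(
                        "tip branch without length: "
                        f"{edge.head_node.taxon.label if edge.head_node.taxon else '?'}"
                    )
            else:
                edge.length = epsilon
        if edge.length is not None and edge.length < 0:
            raise ValidationError("negative branch length in tree")
    return work


def independent_contrasts(
    tree: PhyloTree,
    values: Mapping[str, float],
    polytomy_epsilon: float = DEFAULT_POLYTOMY_EPSILON,
) -> ContrastSet:
    """Felsenstein's standardized independent contrasts for one trait.

    ``values`` maps tip label -> trait value (every tip must be present).
    Polytomies are resolved arbitrarily with ``polytomy_epsilon``-length
    internal branches.  For a bifurcating tree with T tips this yields
    T - 1 contrasts, in post-order.
    """
    work = _prepare_tree(tree, polytomy_epsilon)
    missing = [l.taxon.label for l in work.leaf_node_iter() if l.taxon.label not in values]
    if missing:
        raise ValidationError("missing trait value for tip(s): " + ", ".join(missing))

    node_ids: list[str] = []
    contrasts: list[float] = []
    expected_sd: list[float] = []
    state: dict[int, tuple[float, float]] = {}  # node -> (value, working branch length)
    counter = 0
    for node in work.postorder_node_iter():
        if node.is_leaf():
            state[id(node)] = (float(values[node.taxon.label]), float(node.edge.length))
            continue
        children = node.child_nodes()
        # after resolve_polytomies every internal node is binary
        (x1, v1), (x2, v2) = state[id(children[0])], state[id(children[1])]
        vsum = v1 + v2
        if vsum <= 0:
            raise ValidationError("zero summed branch length at an internal node")
        sd = float(np.sqrt(vsum))
        contrasts.append((x1 - x2) / sd)
        expected_sd.append(sd)
        node_ids.append(f"n{counter}")
        counter += 1
        value = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        extra = v1 * v2 / vsum
        own = float(node.edge.length) if node.parent_node is not None else 0.0
        state[id(node)] = (value, own + extra)
    return ContrastSet(tuple(node_ids), tuple(contrasts), tuple(expected_sd))


def contrast_correlation(a: ContrastSet, b: ContrastSet,
                         centered: bool = False) -> tuple[float, float, float]:
    """Correlation of two contrast sets through the origin (r, F, p).

    Contrast signs are arbitrary, so the conventional statistic is the
    no-intercept correlation r = sum(ab)/sqrt(sum(a^2) sum(b^2)); F is
    reported on (1, n - 2) degrees of freedom.  ``centered=True`` gives the
    ordinary Pearson correlation instead.
    """
    if a.node_ids != b.node_ids:
        raise PairingError("contrast sets come from different trees or node orders")
    x, _ = a.to_arrays()
    y, _ = b.to_arrays()
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 contrasts for a correlation test")
    if centered:
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        denom = float(np.sqrt(np.sum(x * x) * np.sum(y * y)))
        if denom == 0:
            raise ValidationError("all-zero contrasts: correlation undefined")
        r = float(np.sum(x * y) / denom)
    df2 = n - 2
    r2 = min(r * r, 1.0 - 1e-15)
    F = r2 * df2 / (1.0 - r2)
    p = float(stats.f.sf(F, 1, df2))
    return r, F, p


def homoscedasticity_diagnostic(cset: ContrastSet) -> tuple[float, float]:
    """Correlation between |contrast| and its standardizing SD.

    Properly standardized Brownian contrasts show no trend; a significant
    positive correlation flags branch-length misspecification.  Returns
    (r, p) from the Pearson test.
    """
    c, sd = cset.to_arrays()
    if len(c) < 4 or np.std(np.abs(c)) == 0 or np.std(sd) == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(np.abs(c), sd)
    return float(r), float(p)
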