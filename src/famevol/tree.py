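"""Time-calibrated ultrametric species trees.

Branch lengths are stored in thousands of years (ky) as printed in the
calibrated great-ape Y-chromosome trees; rate computations downstream convert
to millions of years (My).  The module wraps dendropy for Newick I/O and adds
TMRCA estimation from pairwise sequence matches plus a UPGMA-style molecular
clock construction from a TMRCA matrix.
"""

from __future__ import annotations

import io
import math

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

__all__ = [
    "TreeError",
    "UltrametricTree",
    "parse_newick",
    "tmrca_from_matches",
    "ultrametric_from_tmrca",
]

KY_PER_MY = 1000.0


class TreeError(ValueError):
    """Malformed Newick input or violated tree invariant."""


class UltrametricTree:
    """Rooted tree with clock-like node ages.

    Thin wrapper around a :class:`dendropy.Tree` that fixes the conventions
    used throughout the package: branch lengths in ky, node ages in ky before
    present, unique tip labels, strictly positive branch lengths.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._validate_structure()
        self._compute_ages()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "UltrametricTree":
        return parse_newick(text)

    # -- invariant checks ---------------------------------------------

    def _validate_structure(self) -> None:
        labels = [lf.taxon.label for lf in self._tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                tok = node.taxon.label if node.taxon else "<internal node>"
                raise TreeError(f"missing branch length at {tok!r}")
            # Tip branches must be strictly positive; internal branches may be
            # zero (polytomy-like ties from the clock construction resolve
            # arbitrarily with zero-length internal edges).
            if node.is_leaf() and node.edge.length <= 0:
                raise TreeError(f"non-positive branch length at {node.taxon.label!r}")
            if not node.is_leaf() and node.edge.length < 0:
                raise TreeError("negative internal branch length")

    def _compute_ages(self) -> None:
        # age = max root-to-tip depth minus depth of the node; for an exactly
        # ultrametric tree every tip has age 0.
        self._depth = {}
        for node in self._tree.preorder_node_iter():
            p = node.parent_node
            self._depth[node] = 0.0 if p is None else self._depth[p] + node.edge.length
        self._height = max(self._depth[lf] for lf in self._tree.leaf_node_iter())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        depths = [self._depth[lf] for lf in self._tree.leaf_node_iter()]
        return (max(depths) - min(depths)) <= rtol * max(depths)

    def validate_ultrametric(self, rtol: float = 1e-6) -> None:
        if not self.is_ultrametric(rtol):
            depths = {lf.taxon.label: self._depth[lf] for lf in self._tree.leaf_node_iter()}
            raise TreeError(f"tree is not ultrametric; root-to-tip depths: {depths}")

    # -- queries -------------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self):
        return self._tree.seed_node

    def node_age(self, node) -> float:
        """Age of a node in ky before present."""
        return self._height - self._depth[node]

    @property
    def root_age(self) -> float:
        return self._height

    def postorder(self):
        return self._tree.postorder_node_iter()

    def preorder(self):
        return self._tree.preorder_node_iter()

    def label_of(self, node) -> str:
        """Tip label, or a stable label for internal nodes (sorted tip sets)."""
        if node.is_leaf():
            return node.taxon.label
        tips = sorted(lf.taxon.label for lf in node.leaf_iter())
        return "(" + ",".join(tips) + ")"

    def branches(self):
        """Yield (child_node, branch_length_ky) for every non-root node."""
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                yield node, node.edge.length

    def tmrca_matrix(self) -> pd.DataFrame:
        """Pairwise node ages of most recent common ancestors, in ky.

        Diagonal is zero; off-diagonal (i, k) is half the patristic distance,
        which for an ultrametric tree equals the age of the MRCA of i and k.
        """
        pdm = self._tree.phylogenetic_distance_matrix()
        labels = self.tip_labels
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        n = len(labels)
        out = np.zeros((n, n))
        for i in range(n):
            for k in range(i + 1, n):
                d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[k]])
                out[i, k] = out[k, i] = d / 2.0
        return pd.DataFrame(out, index=labels, columns=labels)

    # -- output --------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"UltrametricTree(n_tips={self.n_tips}, root_age={self.root_age:.2f} ky)"


def parse_newick(text: str) -> UltrametricTree:
    """Parse a Newick string with mandatory branch lengths.

    A trailing semicolon is optional on input and always emitted on output.
    Raises :class:`TreeError` naming the offending token for malformed input,
    missing branch lengths, or duplicate tips.
    """
    if not isinstance(text, str) or not text.strip():
        raise TreeError("empty Newick string")
    s = text.strip()
    if not s.endswith(";"):
        s += ";"
    try:
        dtree = dendropy.Tree.get(
            data=s,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick string: {exc}") from exc
    if not any(True for _ in dtree.leaf_node_iter()):
        raise TreeError("Newick string contains no tips")
    return UltrametricTree(dtree)


def tmrca_from_matches(length: float, matches: float, mu: float):
    """Time to the most recent common ancestor from pairwise identity.

    TMRCA = ln(L / matches) / (2 mu), with L the number of compared positions,
    ``matches`` the count of identical positions and ``mu`` the per-position
    per-year mutation rate.  Returned in years; non-negative and monotonically
    decreasing in ``matches``.
    """
    length = np.asarray(length, dtype=float)
    matches = np.asarray(matches, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mutation rate mu must be positive")
    if np.any(matches <= 0) or np.any(matches > length):
        raise ValueError("matches must satisfy 0 < matches <= length")
    out = np.log(length / matches) / (2.0 * mu)
    return float(out) if out.ndim == 0 else out


def ultrametric_from_tmrca(tmrca: pd.DataFrame | np.ndarray, labels=None) -> UltrametricTree:
    """Clock tree from a symmetric TMRCA matrix (ky) by average linkage.

    UPGMA agglomeration on the TMRCA matrix: the height of each merge is the
    average TMRCA between the joined groups and becomes the node age directly.
    A matrix of patristic TMRCAs from an existing ultrametric tree is inverted
    exactly (topology and ages).
    """
    if isinstance(tmrca, pd.DataFrame):
        labels = list(tmrca.index)
        mat = tmrca.to_numpy(dtype=float)
    else:
        mat = np.asarray(tmrca, dtype=float)
        if labels is None:
            labels = [f"t{i}" for i in range(mat.shape[0])]
    n = mat.shape[0]
    if mat.shape != (n, n) or not np.allclose(mat, mat.T, rtol=1e-9, atol=1e-9):
        raise TreeError("TMRCA matrix must be square and symmetric")
    if np.any(np.diagonal(mat) != 0) or np.any(mat < 0):
        raise TreeError("TMRCA matrix must be non-negative with zero diagonal")
    if n < 2:
        raise TreeError("need at least two species")

    link = average(squareform(mat, checks=False))
    # Build Newick bottom-up from the linkage matrix; heights are node ages.
    ages = {i: 0.0 for i in range(n)}
    reps = {i: labels[i] for i in range(n)}
    for step, (a, b, height, _cnt) in enumerate(link):
        a, b = int(a), int(b)
        la = format(height - ages[a], ".17g")
        lb = format(height - ages[b], ".17g")
        idx = n + step
        reps[idx] = f"({reps[a]}:{la},{reps[b]}:{lb})"
        ages[idx] = height
    return parse_newick(reps[2 * n - 2] + ";")


def read_tmrca_tsv(path_or_buf) -> pd.DataFrame:
    """Read a TMRCA/distance matrix TSV: first column species, header row species."""
    df = pd.read_csv(path_or_buf, sep="\t", index_col=0)
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    return df


def write_tmrca_tsv(df: pd.DataFrame, path_or_buf) -> None:
    df.to_csv(path_or_buf, sep="\t")
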