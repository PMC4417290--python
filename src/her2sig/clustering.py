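"""Unsupervised clustering validation of a gene signature.

Mirrors the classic microarray validation workflow: restrict a public
expression matrix to the signature genes, log-transform when the values are
evidently on a linear scale, median-center genes then arrays, cluster the
samples agglomeratively on Euclidean distance, cut the dendrogram into two
groups at the final merge, and score the two-group partition against known
response labels using whichever group→label mapping scores higher.

Average linkage (UPGMA) is the default, matching the convention of the
Eisen-style clustering tools this procedure descends from; complete and
single linkage are available. Samples are put in a canonical (sorted-by-id)
order before linkage is computed, which makes the partition invariant to the
column order of the input matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .errors import Her2SigError
from .io import ExpressionMatrix

from .classify import NON_PCR, PCR  # response label constants
from .metrics import ConfusionMatrix

#: max/min ratio above which an unknown-scale matrix is judged linear
LOG_RATIO_THRESHOLD = 50.0

LINKAGES = ("average", "complete", "single")


@dataclass
class ClusterResult:
    """Two-group dendrogram cut with optional label agreement.

    ``linkage`` is a scipy linkage matrix over ``leaf_order`` (samples in
    canonical sorted order); ``assignment`` maps each sample to group 'A' or
    'B', where 'A' is the group containing the alphabetically first sample.
    """

    linkage: np.ndarray
    leaf_order: list[str]
    assignment: dict[str, str]
    label_mapping: dict[str, str] | None = None  # {'A': pCR/non-pCR, 'B': ...}
    agreement: ConfusionMatrix | None = None

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {"A": [], "B": []}
        for s, g in self.assignment.items():
            out[g].append(s)
        return out

    def to_newick(self) -> str:
        """Dendrogram as a Newick string; branch lengths are merge-height gaps."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_order[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist).rsplit(":", 1)[0] + ";"


def maybe_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Log2-transform a matrix judged to be on a linear scale.

    Declared-linear matrices are always transformed; declared-log2 matrices
    are returned untouched. For unknown scale, a max/min ratio above 50 —
    far beyond the dynamic range of log-scale microarray data — triggers
    the transform. Either way the result is declared log2.
    """
    if m.scale_hint == "log2":
        return m
    if m.scale_hint == "unknown":
        vmax = float(m.values.max())
        vmin = float(m.values.min())
        needs = vmin > 0 and vmax / vmin > LOG_RATIO_THRESHOLD
        if not needs:
            return ExpressionMatrix(
                genes=list(m.genes),
                samples=list(m.samples),
                values=m.values.copy(),
                scale_hint="log2",
            )
    if np.any(m.values <= 0):
        raise Her2SigError(
            "log transform requested on a matrix with non-positive values"
        )
    return ExpressionMatrix(
        genes=list(m.genes),
        samples=list(m.samples),
        values=np.log2(m.values),
        scale_hint="log2",
    )


def median_center(
    m: ExpressionMatrix, return_diagnostics: bool = False
):
    """One centering pass: subtract gene-row medians, then sample-column medians.

    After the pass every column median is exactly 0; row medians generally
    drift slightly off 0 and are returned as residual diagnostics when
    requested. The pass is not iterated — a single genes-then-arrays sweep.
    """
    v = m.values.astype(float).copy()
    v -= np.median(v, axis=1, keepdims=True)
    v -= np.median(v, axis=0, keepdims=True)
    out = ExpressionMatrix(
        genes=list(m.genes), samples=list(m.samples), values=v, scale_hint=m.scale_hint
    )
    if return_diagnostics:
        return out, np.median(v, axis=1)
    return out


def hierarchical_two_cut(
    m: ExpressionMatrix, linkage_method: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of samples on Euclidean distance, cut into 2.

    Columns are re-ordered canonically (sorted sample ids) before linkage so
    the partition does not depend on input column order.
    """
    if linkage_method not in LINKAGES:
        raise Her2SigError(
            f"unknown linkage {linkage_method!r}; choose from {LINKAGES}"
        )
    if len(m.samples) < 2:
        raise Her2SigError(
            f"clustering needs at least 2 samples, got {len(m.samples)}"
        )
    if len(set(m.samples)) != len(m.samples):
        raise Her2SigError("duplicate sample identifiers")
    order = sorted(range(len(m.samples)), key=lambda i: m.samples[i])
    leaf_order = [m.samples[i] for i in order]
    X = m.values[:, order].T  # samples x genes
    Z = hierarchy.linkage(X, method=linkage_method, metric="euclidean")
    flat = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    # 'A' = group of the alphabetically first sample (deterministic labels)
    first_group = flat[0]
    assignment = {
        s: ("A" if g == first_group else "B") for s, g in zip(leaf_order, flat)
    }
    return ClusterResult(linkage=Z, leaf_order=leaf_order, assignment=assignment)


def score_against_labels(
    cr: ClusterResult, labels: dict[str, str]
) -> ClusterResult:
    """Attach the best of the two group→response mappings and its confusion.

    Both mappings ({A: pCR, B: non-pCR} and the reverse) are scored; the one
    with higher accuracy is retained (ties prefer A→pCR).
    """
    missing = [s for s in cr.assignment if s not in labels]
    if missing:
        raise Her2SigError(f"samples without response labels: {sorted(missing)}")

    def confusion(mapping: dict[str, str]) -> ConfusionMatrix:
        tp = fn = fp = tn = 0
        for s, g in cr.assignment.items():
            pred, obs = mapping[g], labels[s]
            if obs == PCR:
                tp += pred == PCR
                fn += pred != PCR
            else:
                fp += pred == PCR
                tn += pred != PCR
        return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)

    m1 = {"A": PCR, "B": NON_PCR}
    m2 = {"A": NON_PCR, "B": PCR}
    c1, c2 = confusion(m1), confusion(m2)
    if c1.accuracy_fraction >= c2.accuracy_fraction:
        mapping, cm = m1, c1
    else:
        mapping, cm = m2, c2
    return ClusterResult(
        linkage=cr.linkage,
        leaf_order=cr.leaf_order,
        assignment=dict(cr.assignment),
        label_mapping=mapping,
        agreement=cm,
    )
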