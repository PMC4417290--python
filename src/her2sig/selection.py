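"""Greedy backward gene elimination.

Starting from the full measurement panel, genes are removed one at a time:
each round scores the removal of every remaining gene by the nearest-
reference classification accuracy on a labeled training cohort, and removes
the gene whose removal yields the highest accuracy, provided that accuracy
is at least the current one (accept-on-tie, which drives toward the smallest
panel at equal performance; a strict-improvement mode is available). Ties
among candidate genes are broken alphabetically so the trace is fully
deterministic. Elimination stops when every removal would strictly lower
accuracy, or when the panel reaches ``min_size`` (3 genes — the floor below
which Pearson correlation is undefined).

Accuracy is resubstitution accuracy: the same cohort both guides the search
and scores it, as is natural for signature discovery on a single cohort but
optimistic as an estimate of external performance. A leave-one-out helper is
provided for a less biased estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classify import NON_PCR, PCR, ReferenceSet, correlation_matrix
from .errors import ClassificationError, PanelError
from .io import SENSITIVE
from .panels import GenePanel
from .qpcr import LOG2, ExpressionProfile, in_space

ACCEPT_ON_TIE = "accept-on-tie"
STRICT = "strict"


@dataclass
class SelectionTrace:
    """Ordered record of accepted eliminations.

    ``steps`` holds (eliminated_gene, panel_size_after, accuracy_after) for
    each accepted removal; accuracies are non-decreasing by construction.
    """

    steps: list[tuple[str, int, float]]
    final_panel: GenePanel
    final_accuracy: float
    start_accuracy: float

    def __post_init__(self) -> None:
        accs = [self.start_accuracy] + [a for _, _, a in self.steps]
        if any(b < a for a, b in zip(accs, accs[1:])):
            raise AssertionError("accepted-step accuracies must be non-decreasing")
        sizes = [s for _, s, _ in self.steps]
        if any(b != a - 1 for a, b in zip(sizes, sizes[1:])):
            raise AssertionError("panel size must decrease by exactly 1 per step")

    def write_tsv(self, path: str | Path, sep: str = "\t") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(sep.join(["step", "eliminated_gene", "panel_size", "accuracy"]) + "\n")
            for i, (gene, size, acc) in enumerate(self.steps, start=1):
                fh.write(sep.join([str(i), gene, str(size), f"{acc:.6f}"]) + "\n")


class _CohortMatrices:
    """Cohort and reference profiles as aligned matrices for fast re-scoring."""

    def __init__(self, profiles, labels, refs: ReferenceSet, space: str):
        self.genes = list(refs.panel.genes)
        self.gene_index = {g: i for i, g in enumerate(self.genes)}
        self.X = np.array(
            [in_space(p, space).vector(self.genes) for p in profiles]
        )
        self.y_pcr = np.array(
            [labels[p.sample_id] == PCR for p in profiles], dtype=bool
        )
        refs_s = refs.in_space(space)
        self.R = np.array([p.vector(self.genes) for _, _, p in refs_s.references])
        self.ref_sensitive = np.array(
            [lab == SENSITIVE for _, lab, _ in refs_s.references], dtype=bool
        )

    def accuracy(self, genes) -> float:
        """Fraction of samples whose nearest-reference call matches the label.

        Conservative tie rule: a sample whose best sensitive and best
        resistant correlations are exactly equal is called non-pCR.
        """
        idx = [self.gene_index[g] for g in genes]
        C = correlation_matrix(self.X[:, idx], self.R[:, idx])
        sens_best = C[:, self.ref_sensitive].max(axis=1)
        res_best = C[:, ~self.ref_sensitive].max(axis=1)
        pred_pcr = sens_best > res_best
        return float(np.mean(pred_pcr == self.y_pcr))


def _check_labels(profiles, labels) -> None:
    missing = [p.sample_id for p in profiles if p.sample_id not in labels]
    if missing:
        raise ClassificationError(f"samples without labels: {missing}")
    bad = {labels[p.sample_id] for p in profiles} - {PCR, NON_PCR}
    if bad:
        raise ClassificationError(f"invalid response labels: {sorted(bad)}")


def evaluate_panel(
    panel: GenePanel,
    profiles: list[ExpressionProfile],
    labels: dict[str, str],
    refs: ReferenceSet,
    space: str = LOG2,
) -> float:
    """Classification accuracy of the nearest-reference rule on one panel."""
    if len(panel) < 3:
        raise PanelError(
            f"panel {panel.name!r} has {len(panel)} genes; correlation needs ≥ 3"
        )
    _check_labels(profiles, labels)
    mats = _CohortMatrices(profiles, labels, refs, space)
    missing = [g for g in panel.genes if g not in mats.gene_index]
    if missing:
        raise PanelError(f"panel genes absent from references: {missing}")
    return mats.accuracy(panel.genes)


def backward_eliminate(
    start_panel: GenePanel,
    profiles: list[ExpressionProfile],
    labels: dict[str, str],
    refs: ReferenceSet,
    space: str = LOG2,
    min_size: int = 3,
    mode: str = ACCEPT_ON_TIE,
) -> SelectionTrace:
    """Greedy backward elimination maximising cohort accuracy."""
    if min_size < 3:
        raise PanelError(f"min_size must be ≥ 3 (Pearson floor), got {min_size}")
    if mode not in (ACCEPT_ON_TIE, STRICT):
        raise PanelError(f"unknown elimination mode {mode!r}")
    if len(start_panel) < min_size:
        raise PanelError(
            f"start panel has {len(start_panel)} genes, fewer than min_size={min_size}"
        )
    _check_labels(profiles, labels)
    mats = _CohortMatrices(profiles, labels, refs, space)
    missing = [g for g in start_panel.genes if g not in mats.gene_index]
    if missing:
        raise PanelError(f"start panel genes absent from references: {missing}")

    current = list(start_panel.genes)
    current_acc = mats.accuracy(current)
    start_acc = current_acc
    steps: list[tuple[str, int, float]] = []

    while len(current) > min_size:
        best_gene = None
        best_acc = -1.0
        for gene in sorted(current):  # alphabetical scan fixes the tie-break
            remaining = [g for g in current if g != gene]
            acc = mats.accuracy(remaining)
            if acc > best_acc:
                best_acc, best_gene = acc, gene
        accept = best_acc >= current_acc if mode == ACCEPT_ON_TIE else best_acc > current_acc
        if not accept:
            break
        current = [g for g in current if g != best_gene]
        current_acc = best_acc
        steps.append((best_gene, len(current), current_acc))

    final_panel = start_panel.subset(current, name=f"{start_panel.name}_selected")
    return SelectionTrace(
        steps=steps,
        final_panel=final_panel,
        final_accuracy=current_acc,
        start_accuracy=start_acc,
    )


def exhaustive_best_subset(
    start_panel: GenePanel,
    profiles: list[ExpressionProfile],
    labels: dict[str, str],
    refs: ReferenceSet,
    space: str = LOG2,
    min_size: int = 3,
) -> tuple[GenePanel, float]:
    """Best-accuracy subset over all subsets of size ≥ min_size.

    Exponential in panel size; intended as an oracle for small panels
    (≤ ~12 genes). Ties prefer smaller subsets, then lexicographic gene
    order, for determinism.
    """
    from itertools import combinations

    if len(start_panel) > 16:
        raise PanelError("exhaustive search is only feasible for small panels")
    _check_labels(profiles, labels)
    mats = _CohortMatrices(profiles, labels, refs, space)
    genes = list(start_panel.genes)
    best_acc = -1.0
    best_subset: tuple[str, ...] | None = None
    for k in range(min_size, len(genes) + 1):
        for combo in combinations(sorted(genes), k):
            acc = mats.accuracy(list(combo))
            if acc > best_acc:
                best_acc, best_subset = acc, combo
    assert best_subset is not None
    return start_panel.subset(best_subset, name=f"{start_panel.name}_best"), best_acc


def leave_one_out_accuracy(
    start_panel: GenePanel,
    profiles: list[ExpressionProfile],
    labels: dict[str, str],
    refs: ReferenceSet,
    space: str = LOG2,
    min_size: int = 3,
    mode: str = ACCEPT_ON_TIE,
) -> float:
    """Less biased accuracy: re-run elimination with each sample held out,
    then classify the held-out sample on the panel selected without it."""
    _check_labels(profiles, labels)
    correct = 0
    for i, held_out in enumerate(profiles):
        rest = profiles[:i] + profiles[i + 1 :]
        trace = backward_eliminate(
            start_panel, rest, labels, refs, space, min_size, mode
        )
        mats = _CohortMatrices([held_out], labels, refs, space)
        correct += mats.accuracy(trace.final_panel.genes) == 1.0
    return correct / len(profiles)
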