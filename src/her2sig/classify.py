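"""Nearest-reference correlation classifier.

A tumor is compared against a bank of reference expression profiles from
trastuzumab-sensitive and trastuzumab-resistant HER2+ breast cancer cell
lines. The tumor's panel profile is correlated (Pearson, by default on the
log2 / −ΔCt scale) with each reference; the reference whose correlation is
nearest to 1 determines the call: a sensitive best reference predicts
pathological complete response (pCR), a resistant one predicts non-pCR.

Correlation is computed on the log2 scale by default because raw 2^-ΔCt
values span orders of magnitude and a single high expressor would dominate
a linear-space Pearson. Linear-space correlation remains available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ClassificationError, InputFormatError, ProfileError
from .io import RESISTANT, SENSITIVE, VALID_LABELS
from .panels import GenePanel, normalize_gene_symbol
from .qpcr import LOG2, ExpressionProfile, in_space

PCR = "pCR"
NON_PCR = "non-pCR"
AMBIGUOUS = "ambiguous"

#: sensitivity tag of the winning reference -> predicted response label
LABEL_FROM_SENSITIVITY = {SENSITIVE: PCR, RESISTANT: NON_PCR}

TIE_CONSERVATIVE = "conservative"  # cross-class tie -> non-pCR
TIE_REPORT = "report"  # cross-class tie -> ambiguous


@dataclass
class ReferenceSet:
    """Named cell-line profiles, each tagged sensitive or resistant."""

    references: list[tuple[str, str, ExpressionProfile]]

    def __post_init__(self) -> None:
        names = [n for n, _, _ in self.references]
        if len(set(names)) != len(names):
            raise ClassificationError("duplicate cell-line names in reference set")
        labels = {lab for _, lab, _ in self.references}
        bad = labels - set(VALID_LABELS)
        if bad:
            raise ClassificationError(f"invalid sensitivity labels: {sorted(bad)}")
        if SENSITIVE not in labels or RESISTANT not in labels:
            raise ClassificationError(
                "reference set needs at least one sensitive and one resistant cell line"
            )
        panels = {tuple(p.panel.genes) for _, _, p in self.references}
        if len(panels) != 1:
            raise ClassificationError("reference profiles span different panels")

    @property
    def panel(self) -> GenePanel:
        return self.references[0][2].panel

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.references]

    def sensitivity(self, name: str) -> str:
        for n, lab, _ in self.references:
            if n == name:
                return lab
        raise ClassificationError(f"unknown reference {name!r}")

    def restricted(self, panel: GenePanel) -> "ReferenceSet":
        return ReferenceSet(
            [(n, lab, p.restricted(panel)) for n, lab, p in self.references]
        )

    def in_space(self, space: str) -> "ReferenceSet":
        return ReferenceSet(
            [(n, lab, in_space(p, space)) for n, lab, p in self.references]
        )


@dataclass
class ClassificationResult:
    """Per-sample correlations with every reference plus the response call."""

    sample_id: str
    correlations: dict[str, float]
    best_reference: str
    predicted_label: str
    correlation_space: str = LOG2

    @property
    def best_correlation(self) -> float:
        return self.correlations[self.best_reference]


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient.

    Requires equal-length vectors of at least 3 points, neither constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ClassificationError(
            f"correlation needs equal-length 1-D vectors, got {x.shape} vs {y.shape}"
        )
    if x.size < 3:
        raise ClassificationError(
            f"correlation needs at least 3 points, got {x.size}"
        )
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt(xc @ xc))
    ny = float(np.sqrt(yc @ yc))
    if nx == 0.0 or ny == 0.0:
        raise ClassificationError(
            "correlation undefined for a constant vector (all panel genes equal)"
        )
    r = float((xc @ yc) / (nx * ny))
    return max(-1.0, min(1.0, r))


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson on midranks.

    An alternative to :func:`pearson` that is robust to monotone
    distortions of the expression scale.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pearson(stats.rankdata(x), stats.rankdata(y))


CORRELATION_MEASURES = {"pearson": pearson, "spearman": spearman}


def _decide(correlations: dict[str, float], refs: ReferenceSet, tie_policy: str):
    """Argmax-nearest-to-1 decision with deterministic tie handling.

    Within a sensitivity class, ties go to the alphabetically first cell
    line. Across classes, the conservative policy calls non-pCR and the
    report policy emits an ambiguous label.
    """
    best_r = max(correlations.values())
    winners = sorted(n for n, r in correlations.items() if r == best_r)
    classes = {refs.sensitivity(n) for n in winners}
    if len(classes) == 1:
        best = winners[0]
        return best, LABEL_FROM_SENSITIVITY[classes.pop()]
    # cross-class tie
    resistant_winner = next(n for n in winners if refs.sensitivity(n) == RESISTANT)
    if tie_policy == TIE_CONSERVATIVE:
        return resistant_winner, NON_PCR
    if tie_policy == TIE_REPORT:
        return resistant_winner, AMBIGUOUS
    raise ClassificationError(f"unknown tie policy {tie_policy!r}")


def classify_sample(
    profile: ExpressionProfile,
    refs: ReferenceSet,
    space: str = LOG2,
    tie_policy: str = TIE_CONSERVATIVE,
    measure: str = "pearson",
) -> ClassificationResult:
    """Correlate one tumor profile with every reference and call the response."""
    try:
        corr = CORRELATION_MEASURES[measure]
    except KeyError:
        raise ClassificationError(
            f"unknown correlation measure {measure!r}; "
            f"choose from {sorted(CORRELATION_MEASURES)}"
        ) from None
    missing = [g for g in refs.panel.genes if g not in profile.values]
    if missing:
        raise ClassificationError(
            f"sample {profile.sample_id!r} lacks panel genes: {missing}"
        )
    genes = refs.panel.genes
    p = in_space(profile, space)
    x = p.vector(genes)
    correlations: dict[str, float] = {}
    for name, _, ref_profile in refs.in_space(space).references:
        try:
            correlations[name] = corr(x, ref_profile.vector(genes))
        except ClassificationError as e:
            raise ClassificationError(
                f"sample {profile.sample_id!r} vs reference {name!r} over panel "
                f"{refs.panel.name!r}: {e}"
            ) from None
    best, label = _decide(correlations, refs, tie_policy)
    return ClassificationResult(
        sample_id=profile.sample_id,
        correlations=correlations,
        best_reference=best,
        predicted_label=label,
        correlation_space=space,
    )


@dataclass
class CohortClassification:
    """Results for every successfully classified sample plus collected errors."""

    results: list[ClassificationResult]
    failures: list[tuple[str, str]] = field(default_factory=list)  # (sample, message)


def classify_cohort(
    profiles,
    refs: ReferenceSet,
    space: str = LOG2,
    tie_policy: str = TIE_CONSERVATIVE,
    measure: str = "pearson",
) -> CohortClassification:
    """Classify each profile independently; per-sample errors are collected,
    not fatal, so one bad sample does not sink a cohort run."""
    results: list[ClassificationResult] = []
    failures: list[tuple[str, str]] = []
    for profile in profiles:
        try:
            results.append(
                classify_sample(profile, refs, space, tie_policy, measure)
            )
        except (ClassificationError, ProfileError) as e:
            failures.append((profile.sample_id, str(e)))
    return CohortClassification(results=results, failures=failures)


# ---------------------------------------------------------------------------
# vectorised internals shared with gene selection

def correlation_matrix(X: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations between samples X (n x g) and refs R (m x g)."""
    if X.shape[1] < 3:
        raise ClassificationError(
            f"correlation needs at least 3 genes, got {X.shape[1]}"
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    Rc = R - R.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    rn = np.linalg.norm(Rc, axis=1)
    if np.any(xn == 0) or np.any(rn == 0):
        raise ClassificationError("correlation undefined for a constant profile")
    return np.clip((Xc @ Rc.T) / np.outer(xn, rn), -1.0, 1.0)


# ---------------------------------------------------------------------------
# reference-set I/O (wide TSV: cell_line, label, then one column per gene)

def read_reference_set(
    path: str | Path, panel: GenePanel | None = None, sep: str = "\t"
) -> ReferenceSet:
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"reference set not found: {path}")
    df = pd.read_csv(path, sep=sep)
    if "cell_line" not in df.columns or "label" not in df.columns:
        raise InputFormatError(
            f"{path}: expected columns cell_line, label, <genes...>"
        )
    gene_cols = [c for c in df.columns if c not in ("cell_line", "label")]
    genes = tuple(normalize_gene_symbol(g) for g in gene_cols)
    if panel is None:
        panel = GenePanel(name=path.stem, genes=genes)
    refs = []
    for _, row in df.iterrows():
        values = {
            normalize_gene_symbol(g): float(row[g])
            for g in gene_cols
        }
        profile = ExpressionProfile(
            sample_id=str(row["cell_line"]),
            panel=panel,
            values=values,
            space=LOG2,
        )
        refs.append((str(row["cell_line"]), str(row["label"]).strip(), profile))
    return ReferenceSet(refs)


def write_reference_set(refs: ReferenceSet, path: str | Path, sep: str = "\t") -> None:
    genes = refs.panel.genes
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["cell_line", "label", *genes]) + "\n")
        for name, lab, p in refs.in_space(LOG2).references:
            fh.write(
                sep.join([name, lab, *(repr(float(p.values[g])) for g in genes)]) + "\n"
            )


def write_classification_tsv(
    cohort: CohortClassification, refs: ReferenceSet, path: str | Path, sep: str = "\t"
) -> None:
    """One row per sample: correlations per cell line, best reference, label."""
    names = refs.names
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["sample", *names, "best_reference", "predicted_label"]) + "\n")
        for res in cohort.results:
            fh.write(
                sep.join(
                    [
                        res.sample_id,
                        *(f"{res.correlations[n]:.6f}" for n in names),
                        res.best_reference,
                        res.predicted_label,
                    ]
                )
                + "\n"
            )
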