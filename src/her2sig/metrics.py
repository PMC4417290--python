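"""Prediction-performance metrics and small-sample statistics.

Covers three needs of the pipeline: confusion-matrix summaries of observed
vs predicted response (sensitivity, specificity, PPV, NPV, accuracy, with
percentages rounded half-up); a two-group Mann–Whitney U test for per-gene
expression differences (exact by enumeration for small samples, normal
approximation with tie correction otherwise); and paired per-gene Pearson
concordance between matched measurements, e.g. frozen vs FFPE aliquots of
the same tumors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .classify import AMBIGUOUS, NON_PCR, PCR, pearson
from .errors import Her2SigError

#: combined sample size at or below which the U test is exact by enumeration
EXACT_ENUMERATION_LIMIT = 20


def _percent(fraction: float) -> int:
    """Render a fraction as a whole percentage, halves up, via a one-decimal
    intermediate (0.8148 -> 81.5 -> 82).

    The two-stage rounding matches how clinical 2x2 tables are typically
    typeset from spreadsheet output: the percentage is first rounded to one
    decimal, then to an integer, so e.g. 22/27 renders as 82 rather than 81.
    """
    tenth = math.floor(fraction * 1000.0 + 0.5) / 10.0
    return int(math.floor(tenth + 0.5))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Observed vs predicted pCR / non-pCR counts.

    pCR is the positive class: tp = observed pCR predicted pCR,
    fn = observed pCR predicted non-pCR, fp = observed non-pCR predicted
    pCR, tn = observed non-pCR predicted non-pCR.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise Her2SigError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy_fraction(self) -> float:
        if self.total == 0:
            raise Her2SigError("empty confusion matrix")
        return (self.tp + self.tn) / self.total


@dataclass(frozen=True)
class MetricReport:
    """Fractions (None where the denominator is zero) plus whole-number
    percentage renderings."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float

    @property
    def percentages(self) -> dict[str, int | None]:
        return {
            name: (None if frac is None else _percent(frac))
            for name, frac in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
                ("accuracy", self.accuracy),
            )
        }

    def render_text(self, cm: "ConfusionMatrix | None" = None) -> str:
        """Human-readable block mirroring a clinical 2x2 report."""
        lines = []
        if cm is not None:
            lines += [
                "                 Predicted",
                "               pCR  non-pCR  Total",
                f"Observed pCR    {cm.tp:3d}   {cm.fn:4d}   {cm.tp + cm.fn:4d}",
                f"     non-pCR    {cm.fp:3d}   {cm.tn:4d}   {cm.fp + cm.tn:4d}",
                f"       Total    {cm.tp + cm.fp:3d}   {cm.fn + cm.tn:4d}   {cm.total:4d}",
                "",
            ]
        pct = self.percentages
        for label, key in (
            ("Sensitivity", "sensitivity"),
            ("Specificity", "specificity"),
            ("Positive predictive value", "ppv"),
            ("Negative predictive value", "npv"),
            ("Accuracy", "accuracy"),
        ):
            p = pct[key]
            lines.append(f"{label:27s} {'undefined' if p is None else f'{p}%'}")
        return "\n".join(lines)


def confusion_from_results(
    results, labels: dict[str, str], ambiguous_policy: str = "error"
) -> ConfusionMatrix:
    """Tally observed vs predicted labels from classification results.

    ``ambiguous_policy``: 'error' (default) refuses ambiguous predictions;
    'as_non_pcr' counts them as non-pCR calls; 'exclude' drops them.
    """
    if ambiguous_policy not in ("error", "as_non_pcr", "exclude"):
        raise Her2SigError(f"unknown ambiguous policy {ambiguous_policy!r}")
    tp = fn = fp = tn = 0
    for res in results:
        if res.sample_id not in labels:
            raise Her2SigError(f"sample {res.sample_id!r} has no observed label")
        obs = labels[res.sample_id]
        if obs not in (PCR, NON_PCR):
            raise Her2SigError(f"invalid observed label {obs!r} for {res.sample_id!r}")
        pred = res.predicted_label
        if pred == AMBIGUOUS:
            if ambiguous_policy == "error":
                raise Her2SigError(
                    f"ambiguous prediction for {res.sample_id!r}; set an "
                    f"ambiguous policy to count or exclude it"
                )
            if ambiguous_policy == "exclude":
                continue
            pred = NON_PCR
        if obs == PCR:
            tp += pred == PCR
            fn += pred != PCR
        else:
            fp += pred == PCR
            tn += pred != PCR
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def metric_report(cm: ConfusionMatrix) -> MetricReport:
    """Standard 2x2 summary; zero-denominator metrics are undefined (None)."""
    if cm.total == 0:
        raise Her2SigError("empty confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return MetricReport(
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        ppv=ratio(cm.tp, cm.tp + cm.fp),
        npv=ratio(cm.tn, cm.tn + cm.fn),
        accuracy=cm.accuracy_fraction,
    )


def _u_statistic(ranks_a_sum: float, n_a: int) -> float:
    return ranks_a_sum - n_a * (n_a + 1) / 2.0


def per_gene_rank_test(group_a, group_b) -> float:
    """Two-sided Mann–Whitney U p-value for a location difference.

    For combined n ≤ 20 the p-value is exact: every assignment of the
    pooled observations into two groups of the observed sizes is
    enumerated (midranks handle ties), and p is the probability of a U at
    least as far from its null mean n₁n₂/2 as the observed U. Above n = 20
    the normal approximation with tie correction and continuity correction
    is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise Her2SigError("rank test requires two non-empty groups")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise Her2SigError("rank test requires finite values")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    if n <= EXACT_ENUMERATION_LIMIT:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)  # midranks for ties
        mu = n_a * n_b / 2.0
        u_obs = _u_statistic(float(ranks[:n_a].sum()), n_a)
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        for idx in combinations(range(n), n_a):
            u = _u_statistic(float(ranks[list(idx)].sum()), n_a)
            # tiny epsilon guards float midrank sums in the >= comparison
            hits += abs(u - mu) >= dev_obs - 1e-9
            total += 1
        return hits / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


@dataclass(frozen=True)
class GeneConcordance:
    """Paired Pearson correlation for one gene plus the pairing size."""

    r: float
    n_shared: int


def paired_gene_correlation(
    pairs_a: dict[str, float], pairs_b: dict[str, float]
) -> GeneConcordance:
    """Pearson r for one gene between two matched measurement series.

    Samples are paired by identifier; only samples present in both series
    contribute, and at least 3 shared samples are required.
    """
    shared = sorted(set(pairs_a) & set(pairs_b))
    if len(shared) < 3:
        raise Her2SigError(
            f"paired correlation needs ≥ 3 shared samples, got {len(shared)}"
        )
    x = [pairs_a[s] for s in shared]
    y = [pairs_b[s] for s in shared]
    return GeneConcordance(r=pearson(x, y), n_shared=len(shared))


def concordance_by_gene(profiles_a, profiles_b) -> dict[str, GeneConcordance]:
    """Per-gene paired concordance across two matched profile cohorts
    (e.g. frozen vs FFPE), pairing samples by id."""
    by_id_b = {p.sample_id: p for p in profiles_b}
    genes = profiles_a[0].panel.genes if profiles_a else ()
    out = {}
    for gene in genes:
        pa = {p.sample_id: p.values[gene] for p in profiles_a}
        pb = {
            sid: prof.values[gene]
            for sid, prof in by_id_b.items()
            if gene in prof.values
        }
        out[gene] = paired_gene_correlation(pa, pb)
    return out
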