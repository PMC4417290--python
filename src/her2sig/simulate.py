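"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure the classifier assumes:
two class archetypes (trastuzumab-sensitive and -resistant) defined over a
gene panel in log2 relative-expression space, cell-line references and
tumors drawn as archetype + independent Gaussian noise, uninformative genes
sharing a common mean, and an FFPE degradation effect (multiplicative
attenuation of the log2 signal plus extra noise) applied to paired samples.
Gaussian noise in log2 space is equivalent to log-normal expression, the
standard working model for expression variability.

Defaults mirror the study the pipeline targets: a 45-tumor cohort with a
pCR fraction of 18/45, a 28-gene measurement panel of which 8 genes carry
the class difference, an archetype separation of 2 log2 units against unit
log2 noise, and a baseline log2 relative expression of −12 (ΔCt ≈ 12
cycles against the 18S reference, typical of moderately expressed mRNAs).

All randomness flows through per-operation streams derived from the
mandatory config seed; no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classify import NON_PCR, PCR, ReferenceSet
from .errors import Her2SigError
from .io import RESISTANT, SENSITIVE, CtTable
from .panels import GenePanel
from .qpcr import LOG2, ExpressionProfile

#: default log2 relative expression of an average panel gene vs 18S
BASELINE_LOG2 = -12.0

SENSITIVE_LINES = ("BT474", "HCC2218", "UACC-812")
RESISTANT_LINES = ("HCC1419", "HCC1954", "HCC1569")

# per-operation RNG stream offsets
_STREAM_REFERENCES = 1
_STREAM_COHORT = 2
_STREAM_FFPE = 3
_STREAM_CONSTRUCT = 4


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    archetype_separation is the absolute difference, in log2 units, between
    the class means of each informative gene; noise_sd is the per-gene
    biological + technical noise in log2 units; ffpe_attenuation scales the
    centered log2 signal of the FFPE copy and ffpe_extra_sd adds
    degradation noise on top.
    """

    seed: int
    n_tumors: int = 45
    pcr_fraction: float = 18 / 45
    panel_size: int = 28
    n_informative: int = 8
    archetype_separation: float = 2.0
    noise_sd: float = 1.0
    ffpe_attenuation: float = 0.7
    ffpe_extra_sd: float = 1.0
    block_correlation: float = 0.0  # latent-factor corr among informative genes

    def __post_init__(self) -> None:
        if self.n_tumors <= 0 or self.panel_size <= 0:
            raise Her2SigError("n_tumors and panel_size must be positive")
        if not 0.0 <= self.pcr_fraction <= 1.0:
            raise Her2SigError("pcr_fraction must be in [0, 1]")
        if not 0 <= self.n_informative <= self.panel_size:
            raise Her2SigError("n_informative must be ≤ panel_size")
        if self.noise_sd < 0 or self.ffpe_extra_sd < 0:
            raise Her2SigError("noise standard deviations must be ≥ 0")
        if not 0.0 < self.ffpe_attenuation <= 1.0:
            raise Her2SigError("ffpe_attenuation must be in (0, 1]")
        if not 0.0 <= self.block_correlation < 1.0:
            raise Her2SigError("block_correlation must be in [0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def make_panel(cfg: GeneratorConfig) -> GenePanel:
    """Synthetic panel G01..Gnn; the first n_informative genes are informative."""
    width = max(2, len(str(cfg.panel_size)))
    genes = tuple(f"G{i + 1:0{width}d}" for i in range(cfg.panel_size))
    return GenePanel(name=f"synthetic{cfg.panel_size}", genes=genes)


def informative_genes(cfg: GeneratorConfig) -> tuple[str, ...]:
    return make_panel(cfg).genes[: cfg.n_informative]


def archetypes(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """(sensitive, resistant) class mean vectors in log2 space.

    Informative genes alternate direction (up in one class, down in the
    other) so the class difference is not a uniform shift — Pearson
    correlation, being centered, would be blind to a pure offset.
    """
    sens = np.full(cfg.panel_size, BASELINE_LOG2)
    res = np.full(cfg.panel_size, BASELINE_LOG2)
    half = cfg.archetype_separation / 2.0
    for i in range(cfg.n_informative):
        sign = 1.0 if i % 2 == 0 else -1.0
        sens[i] += sign * half
        res[i] -= sign * half
    return sens, res


def _noise(rng: np.random.Generator, cfg: GeneratorConfig, size: int) -> np.ndarray:
    """Gene-wise noise vector; informative genes optionally share a latent factor."""
    eps = rng.normal(0.0, cfg.noise_sd, size)
    if cfg.block_correlation > 0 and cfg.n_informative > 0:
        rho = cfg.block_correlation
        common = rng.normal(0.0, cfg.noise_sd)
        k = cfg.n_informative
        eps[:k] = math.sqrt(1 - rho) * eps[:k] + math.sqrt(rho) * common
    return eps


def _profile(sample_id: str, panel: GenePanel, vec: np.ndarray) -> ExpressionProfile:
    return ExpressionProfile(
        sample_id=sample_id,
        panel=panel,
        values=dict(zip(panel.genes, map(float, vec))),
        space=LOG2,
    )


def make_references(cfg: GeneratorConfig) -> ReferenceSet:
    """Three sensitive + three resistant cell-line profiles (archetype + noise)."""
    rng = cfg.rng(_STREAM_REFERENCES)
    panel = make_panel(cfg)
    sens, res = archetypes(cfg)
    refs = []
    for name in SENSITIVE_LINES:
        refs.append((name, SENSITIVE, _profile(name, panel, sens + _noise(rng, cfg, cfg.panel_size))))
    for name in RESISTANT_LINES:
        refs.append((name, RESISTANT, _profile(name, panel, res + _noise(rng, cfg, cfg.panel_size))))
    return ReferenceSet(refs)


def make_cohort(
    cfg: GeneratorConfig,
) -> tuple[list[ExpressionProfile], dict[str, str]]:
    """Tumor cohort in log2 space with ground-truth response labels.

    round(pcr_fraction * n_tumors) tumors are drawn from the sensitive
    archetype (labelled pCR, listed first), the rest from the resistant
    archetype (non-pCR).
    """
    rng = cfg.rng(_STREAM_COHORT)
    panel = make_panel(cfg)
    sens, res = archetypes(cfg)
    n_pcr = int(round(cfg.pcr_fraction * cfg.n_tumors))
    profiles: list[ExpressionProfile] = []
    labels: dict[str, str] = {}
    width = max(3, len(str(cfg.n_tumors)))
    for i in range(cfg.n_tumors):
        sid = f"T{i + 1:0{width}d}"
        base = sens if i < n_pcr else res
        profiles.append(_profile(sid, panel, base + _noise(rng, cfg, cfg.panel_size)))
        labels[sid] = PCR if i < n_pcr else NON_PCR
    return profiles, labels


def cohort_to_ct_table(
    profiles: list[ExpressionProfile], reference_ct: float = 12.0
) -> CtTable:
    """Render log2 profiles as a raw Ct table.

    Gene Ct = reference Ct − log2 expression, so the 2^-ΔCt round trip
    recovers the intended expression exactly.
    """
    entries: dict[tuple[str, str], list[float]] = {}
    samples = []
    for p in profiles:
        if p.space != LOG2:
            raise Her2SigError(f"profile {p.sample_id!r} must be in log2 space")
        samples.append(p.sample_id)
        entries[(p.sample_id, "18S")] = [reference_ct]
        for g, v in p.values.items():
            entries[(p.sample_id, g)] = [reference_ct - v]
    return CtTable(samples=samples, entries=entries, reference_gene="18S")


def gene_population_variance(cfg: GeneratorConfig, gene_index: int) -> float:
    """Between-tumor variance of one gene's log2 expression in the cohort.

    Informative genes gain mixture variance p(1−p)·d² from the class-mean
    difference d on top of the noise variance.
    """
    var = cfg.noise_sd**2
    if gene_index < cfg.n_informative:
        p = cfg.pcr_fraction
        var += p * (1 - p) * cfg.archetype_separation**2
    return var


def expected_ffpe_correlation(cfg: GeneratorConfig) -> dict[str, float]:
    """Analytic population frozen–FFPE Pearson r per gene.

    With FFPE = a·frozen + e, e ~ N(0, s²): r = a·σ / sqrt(a²σ² + s²)
    where σ² is the gene's between-tumor variance.
    """
    panel = make_panel(cfg)
    a, s = cfg.ffpe_attenuation, cfg.ffpe_extra_sd
    out = {}
    for i, g in enumerate(panel.genes):
        var = gene_population_variance(cfg, i)
        out[g] = a * math.sqrt(var) / math.sqrt(a**2 * var + s**2) if var > 0 else 0.0
    return out


def ffpe_sd_for_target_correlation(
    rho: float, gene_variance: float, attenuation: float = 1.0
) -> float:
    """Extra-noise sd that yields population frozen–FFPE correlation rho."""
    if not 0.0 < rho <= 1.0:
        raise Her2SigError("target correlation must be in (0, 1]")
    return attenuation * math.sqrt(gene_variance * (1.0 / rho**2 - 1.0))


def make_ffpe_pairs(
    profiles: list[ExpressionProfile], cfg: GeneratorConfig
) -> list[ExpressionProfile]:
    """Degraded FFPE copies of frozen profiles, paired by sample id.

    The centered log2 signal is scaled by ffpe_attenuation and
    ffpe_extra_sd noise is added; the gene-wise baseline is preserved so
    FFPE profiles stay in a realistic expression range.
    """
    rng = cfg.rng(_STREAM_FFPE)
    out = []
    for p in profiles:
        if p.space != LOG2:
            raise Her2SigError(f"profile {p.sample_id!r} must be in log2 space")
        vec = np.array([p.values[g] for g in p.panel.genes])
        centered = vec - BASELINE_LOG2
        degraded = (
            BASELINE_LOG2
            + cfg.ffpe_attenuation * centered
            + rng.normal(0.0, cfg.ffpe_extra_sd, vec.size)
        )
        out.append(_profile(p.sample_id, p.panel, degraded))
    return out


def profile_with_correlations(
    refs: ReferenceSet,
    targets: dict[str, float],
    sample_id: str = "constructed",
    seed: int = 0,
) -> ExpressionProfile:
    """Construct a log2 profile with exact Pearson correlations to two references.

    Given target correlations c₁, c₂ to two reference profiles, the profile
    is built in the centered/standardized space as α·z₁ + β·z₂ + γ·w with w
    orthogonal to both references, solving c₁ = α + βρ, c₂ = αρ + β (ρ the
    reference–reference correlation) and choosing γ ≥ 0 to normalise. The
    targets must be jointly feasible (the implied correlation matrix must
    be positive semi-definite), which holds for modest ρ.
    """
    if len(targets) != 2:
        raise Her2SigError("exactly two target correlations are required")
    names = list(targets)
    genes = refs.panel.genes
    if len(genes) < 4:
        raise Her2SigError("construction needs a panel of ≥ 4 genes")
    vecs = {}
    for name, _, p in refs.in_space(LOG2).references:
        if name in targets:
            vecs[name] = p.vector(genes)
    missing = set(names) - set(vecs)
    if missing:
        raise Her2SigError(f"references not in set: {sorted(missing)}")

    def standardize(v: np.ndarray) -> np.ndarray:
        c = v - v.mean()
        n = np.linalg.norm(c)
        if n == 0:
            raise Her2SigError("constant reference profile")
        return c / n

    z1 = standardize(vecs[names[0]])
    z2 = standardize(vecs[names[1]])
    rho = float(z1 @ z2)
    c1, c2 = float(targets[names[0]]), float(targets[names[1]])
    denom = 1.0 - rho**2
    if denom <= 1e-12:
        raise Her2SigError("the two references are collinear")
    alpha = (c1 - c2 * rho) / denom
    beta = (c2 - c1 * rho) / denom
    planar_norm_sq = alpha**2 + beta**2 + 2 * alpha * beta * rho
    if planar_norm_sq > 1.0 + 1e-12:
        raise Her2SigError(
            f"target correlations {c1}, {c2} infeasible with reference "
            f"correlation {rho:.3f}"
        )
    gamma = math.sqrt(max(0.0, 1.0 - planar_norm_sq))
    rng = np.random.default_rng([seed, _STREAM_CONSTRUCT])
    w = rng.normal(size=len(genes))
    w -= w.mean()
    w -= (w @ z1) * z1
    # re-orthogonalize against z2 component orthogonal to z1
    z2p = z2 - rho * z1
    z2p_norm = np.linalg.norm(z2p)
    if z2p_norm > 0:
        z2u = z2p / z2p_norm
        w -= (w @ z2u) * z2u
    wn = np.linalg.norm(w)
    if wn == 0:
        raise Her2SigError("failed to build an orthogonal residual direction")
    w /= wn
    x = alpha * z1 + beta * z2 + gamma * w
    # affine placement into a realistic log2 range; Pearson is unaffected
    vals = BASELINE_LOG2 + 2.0 * x
    return _profile(sample_id, refs.panel, vals)
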