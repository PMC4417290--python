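"""Relative quantification by the 2^-ΔCt method.

A target gene's Ct is compared against the 18S rRNA reference Ct measured in
the same sample: ΔCt = Ct_gene − Ct_reference, and relative expression is
2^-ΔCt. Lower Ct means more template, so expression decreases as Ct rises.
No PCR-efficiency correction is applied (amplification efficiency is assumed
to be 2 per cycle) and there is no ΔΔCt calibrator sample. Technical
replicates are averaged on the Ct scale before ΔCt is formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ProfileError
from .io import CtTable
from .panels import GenePanel

LINEAR = "linear"
LOG2 = "log2"


@dataclass
class ExpressionProfile:
    """One sample's gene -> relative-expression mapping over a panel.

    ``space`` records whether values are raw 2^-ΔCt ratios (``linear``,
    strictly positive) or their base-2 logarithms (``log2``, equal to −ΔCt).
    """

    sample_id: str
    panel: GenePanel
    values: dict[str, float] = field(repr=False)
    space: str = LINEAR

    def __post_init__(self) -> None:
        if self.space not in (LINEAR, LOG2):
            raise ProfileError(f"invalid space {self.space!r}")
        missing = [g for g in self.panel.genes if g not in self.values]
        if missing:
            raise ProfileError(
                f"profile {self.sample_id!r} incomplete: missing {missing}"
            )
        for g in self.panel.genes:
            v = self.values[g]
            if not math.isfinite(v):
                raise ProfileError(
                    f"profile {self.sample_id!r}: non-finite value for {g!r}"
                )
            if self.space == LINEAR and v <= 0:
                raise ProfileError(
                    f"profile {self.sample_id!r}: non-positive linear value "
                    f"{v!r} for {g!r}"
                )

    def vector(self, genes=None) -> np.ndarray:
        """Values as an array in the given gene order (panel order default)."""
        genes = self.panel.genes if genes is None else genes
        try:
            return np.array([self.values[g] for g in genes], dtype=float)
        except KeyError as e:
            raise ProfileError(
                f"profile {self.sample_id!r} lacks gene {e.args[0]!r}"
            ) from None

    def restricted(self, panel: GenePanel) -> "ExpressionProfile":
        """The same profile viewed over a sub-panel."""
        return ExpressionProfile(
            sample_id=self.sample_id,
            panel=panel,
            values={g: self.values[g] for g in panel.genes},
            space=self.space,
        )


def relative_expression(ct_gene: float, ct_reference: float) -> float:
    """2^-(ct_gene − ct_reference); dimensionless, strictly positive."""
    if not (math.isfinite(ct_gene) and math.isfinite(ct_reference)):
        raise ProfileError(
            f"non-finite Ct input: gene={ct_gene!r}, reference={ct_reference!r}"
        )
    return 2.0 ** -(ct_gene - ct_reference)


def profile_from_ct(
    table: CtTable, sample: str, panel: GenePanel
) -> ExpressionProfile:
    """Linear-space profile for one sample from a Ct table.

    Every panel gene and the reference gene must be measured for the sample;
    replicate Ct values are mean-averaged by :meth:`CtTable.ct`.
    """
    if sample not in table.samples:
        raise ProfileError(f"sample {sample!r} not present in Ct table")
    ct_ref = table.ct(sample, table.reference_gene)
    missing = [g for g in panel.genes if not table.has(sample, g)]
    if missing:
        raise ProfileError(
            f"genes {missing} not measured for sample {sample!r}"
        )
    values = {
        gene: relative_expression(table.ct(sample, gene), ct_ref)
        for gene in panel.genes
    }
    return ExpressionProfile(sample_id=sample, panel=panel, values=values, space=LINEAR)


def to_log2(profile: ExpressionProfile) -> ExpressionProfile:
    """Log2-transform a linear profile; note log2(2^-ΔCt) = −ΔCt exactly."""
    if profile.space != LINEAR:
        raise ProfileError(
            f"profile {profile.sample_id!r} is already in {profile.space} space"
        )
    for g, v in profile.values.items():
        if v <= 0:
            raise ProfileError(
                f"profile {profile.sample_id!r}: cannot log-transform "
                f"non-positive value {v!r} for {g!r}"
            )
    return ExpressionProfile(
        sample_id=profile.sample_id,
        panel=profile.panel,
        values={g: math.log2(v) for g, v in profile.values.items()},
        space=LOG2,
    )


def to_linear(profile: ExpressionProfile) -> ExpressionProfile:
    """Inverse of :func:`to_log2`."""
    if profile.space != LOG2:
        raise ProfileError(
            f"profile {profile.sample_id!r} is already in {profile.space} space"
        )
    return ExpressionProfile(
        sample_id=profile.sample_id,
        panel=profile.panel,
        values={g: 2.0**v for g, v in profile.values.items()},
        space=LINEAR,
    )


def in_space(profile: ExpressionProfile, space: str) -> ExpressionProfile:
    """Profile converted to the requested space (identity if already there)."""
    if space not in (LINEAR, LOG2):
        raise ProfileError(f"invalid space {space!r}")
    if profile.space == space:
        return profile
    return to_log2(profile) if space == LOG2 else to_linear(profile)
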