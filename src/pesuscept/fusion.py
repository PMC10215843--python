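"""Fusing the expression classifier's posterior with SNP genotype evidence
into one susceptibility score.

The fusion rule is naive-Bayes on the odds scale: the classifier posterior
is converted to odds, multiplied by one likelihood ratio per genotyped SNP
(case vs control genotype frequency, Haldane-smoothed), and converted back
to a probability. The rule assumes expression and genotype evidence are
independent given disease status; it is an explicit modeling extension, not
a calibrated clinical score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .association import GenotypeCounts

__all__ = ["RiskAssessment", "genotype_likelihood_ratio", "combine"]

_POSTERIOR_CLIP = 1e-6


@dataclass
class RiskAssessment:
    """A combined susceptibility score and the evidence it came from."""

    expression_posterior: float
    likelihood_ratios: list
    combined_posterior: float
    components: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "expression_posterior": self.expression_posterior,
            "likelihood_ratios": list(self.likelihood_ratios),
            "combined_posterior": self.combined_posterior,
            "components": dict(self.components),
        }


def genotype_likelihood_ratio(
    genotype: str, gc: GenotypeCounts, smoothing: float = 0.5
) -> float:
    """Likelihood ratio of one genotype: case frequency over control frequency.

    Each frequency adds ``smoothing`` (default 0.5, Haldane-consistent) per
    genotype cell; with ``smoothing=0`` a zero control cell is an error (the
    ratio would be infinite) and the caller is advised to smooth.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    g = gc.normalize_genotype(genotype)
    labels = gc.genotype_labels()
    k = labels.index(g)
    case = np.asarray(gc.case, dtype=float) + smoothing
    control = np.asarray(gc.control, dtype=float) + smoothing
    if control[k] == 0:
        raise ValueError(
            f"control frequency of {g} is zero; use smoothing > 0 for a finite ratio"
        )
    case_freq = case[k] / case.sum()
    control_freq = control[k] / control.sum()
    if case_freq == 0:
        raise ValueError(
            f"case frequency of {g} is zero; use smoothing > 0 for a finite ratio"
        )
    return float(case_freq / control_freq)


def combine(expr_posterior: float, lrs) -> RiskAssessment:
    """Naive-Bayes fusion: posterior odds = prior odds x product of LRs.

    ``expr_posterior`` outside (0, 1) is clipped to [1e-6, 1-1e-6] with a
    warning. The result is monotone increasing in the posterior and in every
    likelihood ratio; with posterior 0.5 and all ratios 1 the combined score
    is exactly 0.5.
    """
    lrs = [float(x) for x in lrs]
    if any(x <= 0 for x in lrs):
        raise ValueError("likelihood ratios must be positive")
    p = float(expr_posterior)
    if not 0 < p < 1:
        warnings.warn("degenerate expression posterior clipped away from {0,1}")
        p = float(np.clip(p, _POSTERIOR_CLIP, 1 - _POSTERIOR_CLIP))
    odds = p / (1 - p)
    for lr in lrs:
        odds *= lr
    combined = odds / (1 + odds)
    return RiskAssessment(
        expression_posterior=p,
        likelihood_ratios=lrs,
        combined_posterior=float(combined),
        components={"prior_odds": p / (1 - p), "posterior_odds": odds},
    )
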