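"""Training of per-predictor weights and the ensemble disease score.

Six pathogenicity predictors (MutPred, PolyPhen-2 HumDiv, PolyPhen-2
HumVar, PANTHER, PhD-SNP, SNPs&GO) each output a pathogenicity probability
and a qualitative call for an amino-acid substitution.  On a training set
of n variants validated as affecting function, each predictor i earns a
weight

    W_i = (hp_i + cp_i) / (2 n)

where hp_i counts the training mutations on which predictor i attains the
maximal probability among its present peers, and cp_i those it calls
"disease".  The disease score of a new substitution is then the weighted
mean of its predictor probabilities, which lies in [0,1].

Missing predictor slots are excluded together with their weights from both
numerator and denominator (renormalization), never zero-filled; a score is
reported only when at least ``min_predictors`` usable slots remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    MtPriorError,
    PREDICTORS,
    PredictorProfile,
    PredictorWeights,
    Variant,
)

__all__ = ["TrainingSet", "TrainingMember", "train_weights", "disease_score",
           "ConfigurationError"]


class ConfigurationError(MtPriorError):
    pass


@dataclass(frozen=True)
class TrainingMember:
    variant: Variant
    locus: str
    profile: PredictorProfile


@dataclass
class TrainingSet:
    """Variants previously validated as affecting function, with their
    predictor profiles."""

    members: list[TrainingMember] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def train_weights(training: TrainingSet, tie_policy: str = "all") -> PredictorWeights:
    """Compute W_i = (hp_i + cp_i) / (2 n) from a labeled training set.

    tie_policy: "all" (default) gives every predictor attaining the maximal
    probability full hp credit; "split" shares one credit equally among the
    tied predictors (hp then accumulates fractional counts).
    """
    n = len(training)
    if n == 0:
        raise MtPriorError("empty training set")
    if tie_policy not in ("all", "split"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    hp: dict[str, float] = {s: 0 for s in PREDICTORS}
    cp: dict[str, int] = {s: 0 for s in PREDICTORS}
    for member in training.members:
        present = member.profile.present_slots
        if not present:
            raise MtPriorError(
                f"training member {member.variant} has no predictor probabilities"
            )
        top = max(member.profile.probability(s) for s in present)
        winners = [s for s in present if member.profile.probability(s) == top]
        for s in winners:
            hp[s] += 1 if tie_policy == "all" else 1 / len(winners)
        for s in PREDICTORS:
            if member.profile.call(s) == "disease":
                cp[s] += 1
    weights = {s: (hp[s] + cp[s]) / (2 * n) for s in PREDICTORS}
    hp_int = {s: int(hp[s]) if tie_policy == "all" else hp[s] for s in PREDICTORS}
    return PredictorWeights(weights=weights, n_training=n, hp=hp_int, cp=cp)


def disease_score(
    profile: PredictorProfile,
    weights: PredictorWeights,
    min_predictors: int = 3,
) -> float | None:
    """Weighted mean of predictor probabilities; ``None`` when fewer than
    ``min_predictors`` slots carry both a probability and a positive weight."""
    if min_predictors < 1:
        raise ValueError("min_predictors must be >= 1")
    if all(weights.weight(s) == 0 for s in PREDICTORS):
        raise ConfigurationError("all predictor weights are zero")
    usable = [
        s for s in PREDICTORS
        if profile.probability(s) is not None and weights.weight(s) > 0
    ]
    if len(usable) < min_predictors:
        return None
    num = sum(profile.probability(s) * weights.weight(s) for s in usable)
    den = sum(weights.weight(s) for s in usable)
    return num / den
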