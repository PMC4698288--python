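"""Train predictor weights and score an amino-acid substitution.

Builds a toy training set of five validated-pathogenic variants where the
PolyPhen-2 HumDiv slot is always the strongest predictor, trains the
weights W_i = (hp_i + cp_i) / 2n, and scores a new substitution as the
weighted mean of its predictor probabilities.
"""

from mtprior import MtPosition, PredictorProfile, Variant, disease_score
from mtprior.scoring import TrainingMember, TrainingSet, train_weights

SLOTS = ("MP", "PPD", "PPV", "PT", "PS", "SG")

members = []
for i in range(5):
    probs = dict(zip(SLOTS, (0.55, 0.92, 0.85, 0.40, 0.60, 0.65)))
    calls = dict(zip(SLOTS, ("neutral", "disease", "disease", "neutral",
                             "disease", "disease")))
    members.append(TrainingMember(
        Variant(MtPosition(3307 + i), "A", ref="G"), "MT-ND1",
        PredictorProfile(probabilities=probs, calls=calls),
    ))

weights = train_weights(TrainingSet(members))
print("trained weights (hp, cp):")
for slot in SLOTS:
    print(f"  {slot:>3}: W={weights.weight(slot):.3f} "
          f"(hp={weights.hp[slot]}, cp={weights.cp[slot]})")

query = PredictorProfile(
    probabilities=dict(zip(SLOTS, (0.80, 0.95, 0.90, None, 0.70, 0.75)))
)
ds = disease_score(query, weights)
print(f"disease score of query substitution: {ds:.4f}")
# The score is a weighted mean over present slots (the missing PANTHER
# probability is renormalized away); above 0.4311 it would pass the
# canonical score threshold.
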