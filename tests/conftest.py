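import numpy as np
import pytest
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mtprior.core import MtPosition, PredictorProfile, PREDICTORS, Variant
from mtprior.scoring import TrainingMember, TrainingSet


def make_alignment(rows, haplogroups=None):
    """Alignment from a list of equal-length strings."""
    records = []
    for i, seq in enumerate(rows):
        rid = f"seq{i}"
        if haplogroups:
            rid = f"{rid}|{haplogroups[i]}"
        rec = SeqRecord(Seq(seq), id=rid, description="")
        if haplogroups:
            rec.annotations["haplogroup"] = haplogroups[i]
        records.append(rec)
    return MultipleSeqAlignment(records)


def make_profile(probs, calls=None):
    """PredictorProfile from a 6-sequence of probabilities (None = missing)."""
    probabilities = dict(zip(PREDICTORS, probs))
    call_map = dict(zip(PREDICTORS, calls)) if calls else {}
    return PredictorProfile(probabilities=probabilities, calls=call_map)


def make_member(pos, probs, calls=None, locus="MT-ND1"):
    return TrainingMember(
        Variant(MtPosition(pos), "A", ref="G"), locus, make_profile(probs, calls)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_training_set():
    """Five members where slot PPD always wins and always calls disease."""
    members = []
    for i in range(5):
        probs = [0.5, 0.9, 0.6, 0.4, 0.3, 0.2]
        calls = ["neutral", "disease", "disease", "neutral", "unclassified", None]
        members.append(make_member(3307 + i, probs, calls))
    return TrainingSet(members)
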