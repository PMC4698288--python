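"""Majority-rule consensus sequences and per-site nucleotide variability.

A macro-haplogroup consensus sequence (MHCS) is the per-column most frequent
allele over a multi-alignment of healthy genomes from one macro-haplogroup.
Comparing a sample against its MHCS (alongside rCRS and RSRS) backgrounds
out alleles fixed during evolution, so that only rare alleles survive the
first step of the prioritization cascade.

The default variability metric is gap-excluded heterozygosity,
``1 - sum(f_a^2)`` over allele frequencies among non-gap symbols.  It is a
stand-in for database-annotated site variability: tables produced by other
pipelines may carry their own NV column, which downstream filters accept as
primary input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable

from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import MtPriorError

__all__ = [
    "SiteProfile",
    "ConsensusResult",
    "build_consensus",
    "site_variability",
    "consensus_by_haplogroup",
    "UndefinedVariabilityError",
]

NUCLEOTIDES = ("A", "C", "G", "T")
GAP = "-"


class UndefinedVariabilityError(MtPriorError):
    pass


@dataclass
class SiteProfile:
    """Allele counts at one alignment column (1-based ``pos``).

    ``counts`` tallies A/C/G/T, the gap symbol, and "other" (IUPAC ambiguity
    codes, N, etc.); ``n_effective`` counts unambiguous non-gap symbols.
    """

    pos: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_effective(self) -> int:
        return sum(self.counts.get(b, 0) for b in NUCLEOTIDES)

    def frequencies(self) -> dict[str, float]:
        """Allele frequencies among unambiguous non-gap symbols."""
        n = self.n_effective
        if n == 0:
            return {}
        return {b: self.counts.get(b, 0) / n for b in NUCLEOTIDES if self.counts.get(b, 0)}


@dataclass
class ConsensusResult:
    sequence: str
    per_site: list[SiteProfile]
    variability: list[float]

    @property
    def width(self) -> int:
        return len(self.sequence)

    def degapped_sequence(self) -> str:
        return self.sequence.replace(GAP, "")


def _column_profile(alignment: MultipleSeqAlignment, col: int) -> SiteProfile:
    counts: Counter = Counter()
    for record in alignment:
        symbol = str(record.seq[col]).upper()
        if symbol in NUCLEOTIDES or symbol == GAP:
            counts[symbol] += 1
        else:
            counts["other"] += 1
    return SiteProfile(pos=col + 1, counts=dict(counts))


def heterozygosity(profile: SiteProfile) -> float:
    """Gap-excluded heterozygosity 1 - sum(f_a^2); 0 iff monomorphic."""
    freqs = profile.frequencies()
    return 1.0 - sum(f * f for f in freqs.values())


def site_variability(
    profile: SiteProfile, metric: Callable[[SiteProfile], float] = heterozygosity
) -> float:
    """Per-site nucleotide variability under a pluggable metric (in [0,1])."""
    if profile.n_effective == 0:
        raise UndefinedVariabilityError(
            f"column {profile.pos}: no unambiguous non-gap symbols"
        )
    return metric(profile)


def _consensus_symbol(profile: SiteProfile, tie_rule: str, gap_policy: str) -> str:
    if gap_policy == "exclude":
        candidates = {b: profile.counts.get(b, 0) for b in NUCLEOTIDES}
    elif gap_policy == "include":
        candidates = {b: profile.counts.get(b, 0) for b in (*NUCLEOTIDES, GAP)}
    else:
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    best = max(candidates.values(), default=0)
    if best == 0:
        return "N"  # all-gap (or all-ambiguous) column
    tied = sorted(b for b, c in candidates.items() if c == best)
    if len(tied) == 1 or tie_rule == "alphabetical":
        return tied[0]
    if tie_rule == "n":
        return "N"
    raise ValueError(f"unknown tie_rule {tie_rule!r}")


def build_consensus(
    alignment: MultipleSeqAlignment,
    tie_rule: str = "alphabetical",
    gap_policy: str = "exclude",
) -> ConsensusResult:
    """Per-column majority consensus with site profiles and variability.

    Gaps are excluded from the majority vote and from frequencies by
    default; an all-gap column emits "N" (a consensus of genomes should be
    a genome).  Ties resolve alphabetically (deterministic) unless
    ``tie_rule="n"``.
    """
    if len(alignment) == 0:
        raise MtPriorError("empty alignment")
    width = alignment.get_alignment_length()
    per_site = [_column_profile(alignment, c) for c in range(width)]
    sequence = "".join(_consensus_symbol(p, tie_rule, gap_policy) for p in per_site)
    variability = [
        heterozygosity(p) if p.n_effective > 0 else 0.0 for p in per_site
    ]
    return ConsensusResult(sequence=sequence, per_site=per_site, variability=variability)


def consensus_by_haplogroup(
    alignment: MultipleSeqAlignment, **kwargs
) -> dict[str, ConsensusResult]:
    """Partition records by their haplogroup annotation and build one
    consensus per group (records lacking a haplogroup go to group "")."""
    groups: dict[str, list[SeqRecord]] = {}
    for record in alignment:
        hg = record.annotations.get("haplogroup", "")
        groups.setdefault(hg, []).append(record)
    return {
        hg: build_consensus(MultipleSeqAlignment(records), **kwargs)
        for hg, records in groups.items()
    }
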