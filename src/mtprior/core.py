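"""Shared domain types and canonical constants for human mtDNA variant work.

Coordinates are 1-based, closed intervals on the linear 16,569-bp rCRS
numbering (no in-scope feature crosses the origin, so circularity is
ignored).  Missing values are represented by ``None`` everywhere and are
never coerced to 0: an unclassified predictor slot must drop out of the
weighted mean, not pull it toward zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "MT_GENOME_LENGTH",
    "STOP",
    "PREDICTORS",
    "PREDICTOR_NAMES",
    "GENE_MAP",
    "GeneFeature",
    "CodingEffect",
    "MtPosition",
    "Variant",
    "PredictorProfile",
    "PredictorWeights",
    "AnnotatedVariant",
    "Thresholds",
    "mito_translate",
    "gene_at",
    "InvalidCodonError",
    "MtPriorError",
]

#: length of the revised Cambridge Reference Sequence (rCRS, NC_012920)
MT_GENOME_LENGTH = 16569

#: symbol returned by :func:`mito_translate` for stop codons
STOP = "*"

#: fixed predictor order used by every six-slot record
PREDICTORS = ("MP", "PPD", "PPV", "PT", "PS", "SG")

PREDICTOR_NAMES = {
    "MP": "MutPred",
    "PPD": "PolyPhen-2 HumDiv",
    "PPV": "PolyPhen-2 HumVar",
    "PT": "PANTHER",
    "PS": "PhD-SNP",
    "SG": "SNPs&GO",
}

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial


class MtPriorError(Exception):
    """Base class for every error raised by this package."""


class InvalidCodonError(MtPriorError):
    pass


class CodingEffect(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    NON_SYNONYMOUS = "non_synonymous"
    PREMATURE_STOP = "premature_stop"
    FRAMESHIFT = "frameshift"
    NONCODING = "noncoding"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GeneFeature:
    """One of the 13 mtDNA protein-coding genes (1-based closed interval)."""

    name: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: Standard rCRS (NC_012920) annotation of the 13 protein-coding genes.
#: MT-ND6 is encoded on the light (minus) strand; ATP8/ATP6 and ND4L/ND4
#: overlap, and ATP6/CO3 abut sharing position 9207.
GENE_MAP: tuple[GeneFeature, ...] = (
    GeneFeature("MT-ND1", 3307, 4262, "+"),
    GeneFeature("MT-ND2", 4470, 5511, "+"),
    GeneFeature("MT-CO1", 5904, 7445, "+"),
    GeneFeature("MT-CO2", 7586, 8269, "+"),
    GeneFeature("MT-ATP8", 8366, 8572, "+"),
    GeneFeature("MT-ATP6", 8527, 9207, "+"),
    GeneFeature("MT-CO3", 9207, 9990, "+"),
    GeneFeature("MT-ND3", 10059, 10404, "+"),
    GeneFeature("MT-ND4L", 10470, 10766, "+"),
    GeneFeature("MT-ND4", 10760, 12137, "+"),
    GeneFeature("MT-ND5", 12337, 14148, "+"),
    GeneFeature("MT-ND6", 14149, 14673, "-"),
    GeneFeature("MT-CYB", 14747, 15887, "+"),
)

GENES_BY_NAME = {g.name: g for g in GENE_MAP}


@dataclass(frozen=True, order=True)
class MtPosition:
    """1-based coordinate on the 16,569-bp circular rCRS."""

    pos: int

    def __post_init__(self) -> None:
        if not (1 <= self.pos <= MT_GENOME_LENGTH):
            raise ValueError(
                f"mtDNA position must be in [1, {MT_GENOME_LENGTH}], got {self.pos}"
            )

    def __int__(self) -> int:
        return self.pos


class VariantKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True)
class Variant:
    """A single mtDNA variant in rCRS coordinates.

    ``ref`` may be ``None`` when a table prints only the derived allele
    (e.g. "11778A"); identity comparisons downstream key on (pos, alt).
    """

    pos: MtPosition
    alt: str
    ref: str | None = None
    kind: VariantKind = VariantKind.SUBSTITUTION

    def __post_init__(self) -> None:
        if self.kind is VariantKind.SUBSTITUTION:
            if self.ref is not None and self.ref == self.alt:
                raise ValueError(f"substitution with ref == alt at {self.pos.pos}")
            if len(self.alt) != 1 or self.alt not in "ACGT":
                raise ValueError(f"substitution alt must be a single base, got {self.alt!r}")
        if self.kind is VariantKind.INSERTION and not self.alt:
            raise ValueError("insertion requires a non-empty inserted sequence")

    @property
    def key(self) -> tuple[int, str, str]:
        """Identity key: (position, kind, derived allele)."""
        return (self.pos.pos, self.kind.value, self.alt)

    def __str__(self) -> str:
        if self.kind is VariantKind.INSERTION:
            return f"{self.pos.pos}.{self.alt}"
        if self.kind is VariantKind.DELETION:
            return f"{self.pos.pos}del{self.alt}"
        if self.ref is None:
            return f"m.{self.pos.pos}{self.alt}"
        return f"m.{self.pos.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class PredictorProfile:
    """Six pathogenicity-predictor outputs for one amino-acid substitution.

    probabilities: probability of pathogenicity per predictor, keyed by
        :data:`PREDICTORS`; ``None`` marks a missing slot.
    calls: qualitative prediction per predictor, one of "disease",
        "neutral", "unclassified", or ``None``.
    """

    probabilities: dict[str, float | None] = field(default_factory=dict)
    calls: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.probabilities:
            if key not in PREDICTORS:
                raise ValueError(f"unknown predictor slot {key!r}")
        for key, p in self.probabilities.items():
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError(f"probability for {key} out of [0,1]: {p}")
        for key, c in self.calls.items():
            if key not in PREDICTORS:
                raise ValueError(f"unknown predictor slot {key!r}")
            if c is not None and c not in ("disease", "neutral", "unclassified"):
                raise ValueError(f"invalid call for {key}: {c!r}")

    def probability(self, slot: str) -> float | None:
        return self.probabilities.get(slot)

    def call(self, slot: str) -> str | None:
        return self.calls.get(slot)

    @property
    def present_slots(self) -> tuple[str, ...]:
        return tuple(s for s in PREDICTORS if self.probabilities.get(s) is not None)


@dataclass(frozen=True)
class PredictorWeights:
    """Trained per-predictor weights W_i = (hp_i + cp_i) / (2 n).

    hp_i counts training mutations on which predictor i attains the maximal
    probability among present slots; cp_i counts those it calls "disease".
    """

    weights: dict[str, float]
    n_training: int
    hp: dict[str, int]
    cp: dict[str, int]

    def __post_init__(self) -> None:
        for s in PREDICTORS:
            if s not in self.weights:
                raise ValueError(f"missing weight for predictor {s}")
            if not (0.0 <= self.weights[s] <= 1.0):
                raise ValueError(f"weight for {s} out of [0,1]: {self.weights[s]}")

    def weight(self, slot: str) -> float:
        return self.weights[slot]


@dataclass
class AnnotatedVariant:
    """One variant in one sample, carrying every annotation the cascade uses.

    ``hf`` is either a single heteroplasmic fraction or a tuple of per-tissue
    fractions (e.g. blood/tumor); ``None`` means not measured.
    """

    variant: Variant
    locus: str | None = None
    coding_effect: CodingEffect | None = None
    aa_change: str = ""
    nt_variability: float | None = None
    aa_variability: float | None = None
    disease_score: float | None = None
    hf: float | tuple[float, ...] | None = None
    recognized_by: frozenset[str] = frozenset()
    haplogroup_defining: bool | None = None
    sample_id: str = ""
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.disease_score is not None and not (0.0 <= self.disease_score <= 1.0):
            raise ValueError(f"disease score out of [0,1]: {self.disease_score}")
        for h in self.hf_values:
            if not (0.0 <= h <= 1.0):
                raise ValueError(f"heteroplasmic fraction out of [0,1]: {h}")
        if self.nt_variability is not None and self.nt_variability < 0:
            raise ValueError("nucleotide variability must be >= 0")

    @property
    def hf_values(self) -> tuple[float, ...]:
        if self.hf is None:
            return ()
        if isinstance(self.hf, tuple):
            return self.hf
        return (self.hf,)

    @property
    def key(self) -> tuple[int, str, str]:
        return self.variant.key

    def copy(self, **changes) -> "AnnotatedVariant":
        return replace(self, **changes)


@dataclass(frozen=True)
class Thresholds:
    """Canonical cutoffs of the prioritization workflow.

    dst: disease score threshold (variants pass with DS >= dst).
    nvc: nucleotide variability cutoff (variants pass with NV <= nvc).
    hf_cutoff: minimum heteroplasmic fraction, or None to skip the HF step.
    posterior_ratio: posterior-odds level defining the DST (second mixture
        component this many times more probable than the first).
    """

    dst: float = 0.4311
    nvc: float = 0.0026
    hf_cutoff: float | None = None
    posterior_ratio: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dst <= 1.0):
            raise ValueError("dst must lie in [0,1]")
        if self.nvc < 0:
            raise ValueError("nvc must be >= 0")
        if self.hf_cutoff is not None and not (0.0 <= self.hf_cutoff <= 1.0):
            raise ValueError("hf_cutoff must lie in [0,1]")
        if self.posterior_ratio <= 0:
            raise ValueError("posterior_ratio must be > 0")


def mito_translate(codon: str) -> str:
    """Translate a codon under the vertebrate mitochondrial genetic code.

    Returns the one-letter amino acid, or :data:`STOP` for the four stop
    codons (TAA, TAG, AGA, AGG).  ATA encodes M and TGA encodes W, the two
    classic departures from the universal code.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise InvalidCodonError(f"not a valid codon: {codon!r}")
    if codon in _MITO_TABLE.stop_codons:
        return STOP
    return _MITO_TABLE.forward_table[codon]


def gene_at(pos: MtPosition | int) -> list[tuple[str, str, int]]:
    """Protein-coding genes overlapping ``pos``.

    Returns ``[(gene symbol, strand, codon phase)]`` for every overlapping
    gene (two entries inside the ATP8/ATP6 and ND4L/ND4 overlaps), empty for
    non-coding positions.  The codon phase is 0/1/2 within the codon read on
    the coding strand.
    """
    p = pos.pos if isinstance(pos, MtPosition) else MtPosition(pos).pos
    hits: list[tuple[str, str, int]] = []
    for g in GENE_MAP:
        if p in g:
            offset = (g.end - p) if g.strand == "-" else (p - g.start)
            hits.append((g.name, g.strand, offset % 3))
    return hits


def codon_number(gene: str | GeneFeature, pos: int) -> int:
    """1-based codon (amino acid) number of ``pos`` within ``gene``."""
    g = GENES_BY_NAME[gene] if isinstance(gene, str) else gene
    if pos not in g:
        raise ValueError(f"position {pos} outside {g.name}")
    offset = (g.end - pos) if g.strand == "-" else (pos - g.start)
    return offset // 3 + 1


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
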