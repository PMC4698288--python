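"""The stepwise variant prioritization cascade and tumor/normal comparison.

Order of the cascade (each step drops rows, never adds):

1. reference concordance — keep variants recognized simultaneously against
   rCRS, RSRS and the sample's macro-haplogroup consensus (MHCS); alleles
   matching any reference are evolutionary background, not candidates.
2. haplogroup exclusion — drop marker alleles on the path from the
   phylogeny root to the sample's haplogroup.
3. nucleotide variability — keep NV <= NVC (sites under constraint).
4. coding-effect restriction — keep protein-changing classes
   (non-synonymous, premature stop, frameshift).
5. disease score — non-synonymous variants need DS >= DST; truncating
   variants (premature stop / frameshift) bypass the score, since no
   predictor probabilities exist for them.
6. heteroplasmy — keep HF >= cutoff (every tissue, when several are
   recorded), if a cutoff is configured.

Steps default to "auto": a step runs only when the table actually carries
the datum it needs, so published candidate lists that were already
reference/haplogroup-filtered pass through those steps untouched.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from statsmodels.stats.proportion import proportion_confint

from .core import (
    AnnotatedVariant,
    CodingEffect,
    GENE_MAP,
    GeneFeature,
    MtPosition,
    MtPriorError,
    Thresholds,
    Variant,
    VariantKind,
    mito_translate,
    reverse_complement,
    STOP,
)
from .io_tables import MarkerTable, VariantTable

__all__ = [
    "StepMode",
    "CascadeFlags",
    "PrioritizationTrace",
    "PairComparison",
    "recognize_against_references",
    "flag_haplogroup_defining",
    "classify_coding_effect",
    "prioritize",
    "compare_pair",
    "hf_confidence_interval",
    "distinct_variants",
    "ReferenceMismatchError",
]

REFERENCE_NAMES = ("rCRS", "RSRS", "MHCS")

PROTEIN_CHANGING = frozenset(
    {CodingEffect.NON_SYNONYMOUS, CodingEffect.PREMATURE_STOP, CodingEffect.FRAMESHIFT}
)
DS_BYPASS_CLASSES = frozenset({CodingEffect.PREMATURE_STOP, CodingEffect.FRAMESHIFT})


class ReferenceMismatchError(MtPriorError):
    pass


class StepMode(str, enum.Enum):
    AUTO = "auto"  # run iff the table carries the needed datum
    ON = "on"
    OFF = "off"


@dataclass(frozen=True)
class CascadeFlags:
    """Step toggles and edge-case policies of the cascade."""

    reference: StepMode = StepMode.AUTO
    haplogroup: StepMode = StepMode.AUTO
    variability: StepMode = StepMode.AUTO
    coding: StepMode = StepMode.AUTO
    disease_score: StepMode = StepMode.AUTO
    stop_bypass: bool = True  # truncating variants skip the DS filter
    missing_hf_passes: bool = False
    hf_mode: str = "strict"  # "strict" or "ci" (CI-aware when counts exist)
    hf_ci_level: float = 0.95


@dataclass
class PrioritizationTrace:
    """Per-step surviving sets and the final prioritized list."""

    table: VariantTable
    steps: list[tuple[str, list[tuple], int]] = field(default_factory=list)
    prioritized_indices: set[int] = field(default_factory=set)
    row_outcomes: list[dict[str, bool | None]] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)
    flags: CascadeFlags = field(default_factory=CascadeFlags)

    @property
    def prioritized(self) -> list[AnnotatedVariant]:
        return [self.table.rows[i] for i in sorted(self.prioritized_indices)]

    @property
    def counts(self) -> dict[str, int]:
        return {name: count for name, _, count in self.steps}


# ---------------------------------------------------------------------------
# Step 1 helpers: reference concordance

def recognize_against_references(
    variants: list[Variant], rcrs: str, rsrs: str, mhcs: str
) -> list[frozenset[str]]:
    """For each variant, the set of references whose allele differs from the
    sample allele at that position (a variant is "recognized by" reference R
    when it is a change relative to R).

    The concordance filter downstream keeps variants recognized by all
    three: an allele matching even one reference is fixed background.
    """
    refs = {"rCRS": rcrs, "RSRS": rsrs, "MHCS": mhcs}
    lengths = {name: len(seq) for name, seq in refs.items()}
    if len(set(lengths.values())) != 1:
        raise ReferenceMismatchError(f"reference length mismatch: {lengths}")
    out = []
    for v in variants:
        idx = v.pos.pos - 1
        if idx >= lengths["rCRS"]:
            raise ReferenceMismatchError(
                f"position {v.pos.pos} beyond reference length {lengths['rCRS']}"
            )
        if v.kind is not VariantKind.SUBSTITUTION:
            # indels are changes relative to every equal-length reference
            out.append(frozenset(REFERENCE_NAMES))
            continue
        out.append(
            frozenset(
                name for name, seq in refs.items() if seq[idx].upper() != v.alt
            )
        )
    return out


# ---------------------------------------------------------------------------
# Step 2 helpers: haplogroup-defining markers

def flag_haplogroup_defining(
    variants: list[Variant], marker_table: MarkerTable, sample_haplogroup: str
) -> list[bool]:
    """True for variants matching a marker (pos, allele) on the path from
    the phylogeny root to the sample's haplogroup."""
    if len(marker_table) == 0:
        return [False] * len(variants)
    markers = marker_table.markers_for(sample_haplogroup)
    return [v.key in markers for v in variants]


# ---------------------------------------------------------------------------
# Coding-effect classification

_SEVERITY = {
    CodingEffect.PREMATURE_STOP: 3,
    CodingEffect.FRAMESHIFT: 3,
    CodingEffect.NON_SYNONYMOUS: 2,
    CodingEffect.SYNONYMOUS: 1,
}


def _codon_at(reference: str, gene: GeneFeature, pos: int) -> tuple[str, int, int]:
    """Reference codon containing ``pos`` on the coding strand.

    Returns (codon, codon_number, offset-in-codon).  Incomplete terminal
    codons are padded with A (polyadenylation of the transcript completes
    the stop codon).
    """
    if gene.strand == "+":
        offset = pos - gene.start
        codon_idx, codon_off = divmod(offset, 3)
        start = gene.start - 1 + codon_idx * 3
        codon = reference[start:start + 3].upper()
        codon = codon[: gene.end - start]  # clip at gene end
    else:
        offset = gene.end - pos
        codon_idx, codon_off = divmod(offset, 3)
        end = gene.end - codon_idx * 3
        start = max(end - 3, gene.start - 1)
        codon = reverse_complement(reference[start:end].upper())
    codon = (codon + "AAA")[:3]
    return codon, codon_idx + 1, codon_off


def classify_coding_effect(
    variant: Variant,
    reference: str,
    gene_map: tuple[GeneFeature, ...] = GENE_MAP,
) -> tuple[CodingEffect, str]:
    """Classify a variant's protein-level consequence against a reference.

    Substitutions inside protein-coding genes are translated through the
    vertebrate mitochondrial code on the strand-corrected codon; indels
    whose length is not a multiple of 3 are frameshifts (in-frame indels are
    reported as non-synonymous).  At gene overlaps the most severe per-gene
    effect wins.  Returns (effect, amino-acid change like "R340H").
    """
    pos = variant.pos.pos
    genes = [g for g in gene_map if pos in g]
    if not genes:
        return CodingEffect.NONCODING, ""

    if variant.kind is not VariantKind.SUBSTITUTION:
        payload = 0 if variant.alt == "-" else len(variant.alt)
        if variant.kind is VariantKind.DELETION:
            payload = len(variant.ref) if variant.ref else 1
        if payload % 3 != 0:
            return CodingEffect.FRAMESHIFT, "Frameshift"
        return CodingEffect.NON_SYNONYMOUS, ""

    best: tuple[int, CodingEffect, str] | None = None
    for gene in genes:
        codon, codon_number, codon_off = _codon_at(reference, gene, pos)
        ref_base = reference[pos - 1].upper()
        if variant.ref is not None and variant.ref != ref_base:
            raise ReferenceMismatchError(
                f"variant {variant} states ref {variant.ref} but reference has "
                f"{ref_base} at {pos}"
            )
        alt_base = variant.alt if gene.strand == "+" else reverse_complement(variant.alt)
        assert codon[codon_off] == (ref_base if gene.strand == "+"
                                    else reverse_complement(ref_base))
        alt_codon = codon[:codon_off] + alt_base + codon[codon_off + 1:]
        ref_aa = mito_translate(codon)
        alt_aa = mito_translate(alt_codon)
        if ref_aa == alt_aa:
            effect = CodingEffect.SYNONYMOUS
        elif alt_aa == STOP:
            effect = CodingEffect.PREMATURE_STOP
        else:
            effect = CodingEffect.NON_SYNONYMOUS
        aa_change = f"{ref_aa}{codon_number}{alt_aa}"
        candidate = (_SEVERITY[effect], effect, aa_change)
        if best is None or candidate[0] > best[0]:
            best = candidate
    return best[1], best[2]


# ---------------------------------------------------------------------------
# The cascade

def _hf_passes(row: AnnotatedVariant, cutoff: float, flags: CascadeFlags) -> bool:
    values = row.hf_values
    if not values:
        return flags.missing_hf_passes
    if flags.hf_mode == "ci":
        counts = _read_counts(row)
        if counts is not None:
            alt, depth = counts
            _, high = hf_confidence_interval(alt, depth, flags.hf_ci_level)
            return high >= cutoff
    return all(h >= cutoff for h in values)


def _read_counts(row: AnnotatedVariant) -> tuple[int, int] | None:
    try:
        return int(row.annotations["alt_count"]), int(row.annotations["depth"])
    except (KeyError, ValueError):
        return None


def prioritize(
    table: VariantTable,
    thresholds: Thresholds | None = None,
    flags: CascadeFlags | None = None,
) -> PrioritizationTrace:
    """Run the stepwise cascade over an annotated variant table.

    Raises a configuration error when a step is forced ON but no row
    carries the datum it needs.  Step counts along the trace are monotone
    non-increasing; ``prioritize`` is idempotent on its own output.
    """
    thresholds = thresholds or Thresholds()
    flags = flags or CascadeFlags()
    rows = table.rows
    trace = PrioritizationTrace(table=table, thresholds=thresholds, flags=flags)
    trace.row_outcomes = [{} for _ in rows]
    alive = set(range(len(rows)))

    def run_step(name, mode, has_datum, predicate):
        nonlocal alive
        present = any(has_datum(rows[i]) for i in alive)
        if mode is StepMode.OFF or (mode is StepMode.AUTO and not present):
            return
        if mode is StepMode.ON and rows and not present:
            raise MtPriorError(
                f"step {name!r} forced on but no surviving row carries its data"
            )
        survivors = set()
        for i in alive:
            ok = predicate(rows[i])
            trace.row_outcomes[i][name] = ok
            if ok:
                survivors.add(i)
        alive = survivors
        trace.steps.append(
            (name, [rows[i].key for i in sorted(alive)], len(alive))
        )

    all_refs = frozenset(REFERENCE_NAMES)
    run_step(
        "reference",
        flags.reference,
        lambda r: bool(r.recognized_by),
        lambda r: r.recognized_by >= all_refs,
    )
    run_step(
        "haplogroup",
        flags.haplogroup,
        lambda r: r.haplogroup_defining is not None,
        lambda r: r.haplogroup_defining is not True,
    )
    run_step(
        "variability",
        flags.variability,
        lambda r: r.nt_variability is not None,
        lambda r: r.nt_variability is not None and r.nt_variability <= thresholds.nvc,
    )
    run_step(
        "coding",
        flags.coding,
        lambda r: r.coding_effect is not None,
        lambda r: r.coding_effect in PROTEIN_CHANGING,
    )

    def ds_ok(r: AnnotatedVariant) -> bool:
        if flags.stop_bypass and r.coding_effect in DS_BYPASS_CLASSES:
            return True
        return r.disease_score is not None and r.disease_score >= thresholds.dst

    run_step(
        "disease_score",
        flags.disease_score,
        lambda r: r.disease_score is not None
        or r.coding_effect in DS_BYPASS_CLASSES,
        ds_ok,
    )
    if thresholds.hf_cutoff is not None:
        run_step(
            "heteroplasmy",
            StepMode.ON if any(rows[i].hf_values for i in alive) else StepMode.AUTO,
            lambda r: bool(r.hf_values),
            lambda r: _hf_passes(r, thresholds.hf_cutoff, flags),
        )

    trace.prioritized_indices = alive
    return trace


def distinct_variants(rows) -> list[tuple]:
    """Distinct variant keys (pos, kind, allele) across samples, first-seen
    order: recurrent variants count once in distinct-variant summaries."""
    seen: list[tuple] = []
    for row in rows:
        key = row.key if isinstance(row, AnnotatedVariant) else row
        if key not in seen:
            seen.append(key)
    return seen


# ---------------------------------------------------------------------------
# Tumor/normal pairing

@dataclass
class PairComparison:
    """Partition of two same-individual variant sets by (pos, allele) key."""

    tumor_specific: list[AnnotatedVariant]
    germline: list[tuple[AnnotatedVariant, AnnotatedVariant]]  # (tumor, normal)
    normal_specific: list[AnnotatedVariant]
    hf_ci: dict[tuple, dict[str, tuple[float, float]]] = field(default_factory=dict)
    ci_discordant: set[tuple] = field(default_factory=set)

    @property
    def germline_keys(self) -> set[tuple]:
        return {t.key for t, _ in self.germline}


def _index_by_key(table: VariantTable, label: str) -> dict[tuple, AnnotatedVariant]:
    index: dict[tuple, AnnotatedVariant] = {}
    for row in table.rows:
        if row.key in index:
            raise MtPriorError(f"duplicated variant key in {label} table: {row.key}")
        index[row.key] = row
    return index


def compare_pair(
    tumor: VariantTable,
    normal: VariantTable,
    ci_rule: str = "none",
    level: float = 0.95,
) -> PairComparison:
    """Partition tumor and matched-normal variants into tumor-specific,
    germline (shared) and normal-specific sets.

    With ``ci_rule="overlap"`` and read counts available (annotation columns
    ``alt_count``/``depth``), germline calls additionally require the Wilson
    intervals on HF to overlap in the two tissues; shared variants failing
    that are kept germline but listed in ``ci_discordant``.
    """
    if ci_rule not in ("none", "overlap"):
        raise ValueError(f"unknown ci_rule {ci_rule!r}")
    t_index = _index_by_key(tumor, "tumor")
    n_index = _index_by_key(normal, "normal")
    shared = [k for k in t_index if k in n_index]
    result = PairComparison(
        tumor_specific=[t_index[k] for k in t_index if k not in n_index],
        germline=[(t_index[k], n_index[k]) for k in shared],
        normal_specific=[n_index[k] for k in n_index if k not in t_index],
    )
    for k in shared:
        cis = {}
        for label, row in (("tumor", t_index[k]), ("normal", n_index[k])):
            counts = _read_counts(row)
            if counts is not None:
                cis[label] = hf_confidence_interval(*counts, level)
        if cis:
            result.hf_ci[k] = cis
        if ci_rule == "overlap" and len(cis) == 2:
            (lo1, hi1), (lo2, hi2) = cis["tumor"], cis["normal"]
            if max(lo1, lo2) > min(hi1, hi2):
                result.ci_discordant.add(k)
    return result


def hf_confidence_interval(
    alt_count: int, depth: int, level: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for the heteroplasmic fraction alt_count/depth."""
    if depth < 1:
        raise MtPriorError("depth must be >= 1 for a heteroplasmy interval")
    if not (0 <= alt_count <= depth):
        raise MtPriorError("alt_count must lie in [0, depth]")
    low, high = proportion_confint(alt_count, depth, alpha=1 - level, method="wilson")
    return float(low), float(high)
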