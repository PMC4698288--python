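"""Seeded generators for synthetic inputs with the structure the method assumes.

Every stage of the workflow is testable without external data:

* disease-score populations drawn from a two-component normal mixture
  truncated to [0,1] (the bimodal shape of scores over a healthy-population
  variant set: a benign bulk plus a damaging tail);
* annotated cohorts with planted pathogenic variants whose DS/NV/HF land in
  the passing region while background variants are constructed to fail at
  least one filter;
* haplogroup marker trees and matching alignments, where leaf genomes are a
  founder sequence mutated along the root-to-leaf marker path.

All generators are bit-reproducible given their seed.  Truncation of DS
draws is by resampling, not clipping, so no probability mass piles up at 0
or 1 (boundary atoms would distort mixture fits).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AnnotatedVariant,
    CodingEffect,
    GENE_MAP,
    MT_GENOME_LENGTH,
    MtPosition,
    MtPriorError,
    Thresholds,
    Variant,
)
from .io_tables import MarkerTable, VariantTable
from .prioritizer import REFERENCE_NAMES

__all__ = [
    "CohortSpec",
    "TreeSpec",
    "SpecError",
    "generate_ds_population",
    "generate_nv_values",
    "generate_cohort",
    "generate_marker_tree_and_alignment",
    "synthetic_reference",
]

NUCLEOTIDES = "ACGT"


class SpecError(MtPriorError):
    pass


@dataclass(frozen=True)
class PlantedVariant:
    """A pathogenic variant planted into a synthetic cohort with target
    annotation values chosen to clear every cascade filter."""

    variant: Variant
    disease_score: float = 0.85
    nt_variability: float = 0.0005
    hf: float = 0.95
    sample_id: str = ""


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate the validation datasets the workflow was demonstrated
    on: tens of samples carrying ~70 variants each, background disease
    scores from a mixture with components near 0.25 and 0.75 mixing 46:54,
    and right-skewed (exponential) background nucleotide variability.
    """

    n_samples: int = 20
    n_background_variants: int = 70
    planted_pathogenic: tuple[PlantedVariant, ...] = ()
    ds_pi: tuple[float, float] = (0.46, 0.54)
    ds_mu: tuple[float, float] = (0.25, 0.75)
    ds_sigma: tuple[float, float] = (0.07, 0.08)
    nv_scale: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ds_pi) - 1.0) > 1e-9 or any(p <= 0 for p in self.ds_pi):
            raise SpecError("mixture proportions must be positive and sum to 1")
        for pv in self.planted_pathogenic:
            if not (0 <= pv.disease_score <= 1 and 0 <= pv.hf <= 1):
                raise SpecError("planted DS and HF targets must lie in [0,1]")
        keys = [pv.variant.key + (pv.sample_id,) for pv in self.planted_pathogenic]
        if len(keys) != len(set(keys)):
            raise SpecError("planted variant positions collide")


@dataclass(frozen=True)
class TreeSpec:
    """Shape of a synthetic haplogroup tree and its leaf alignment."""

    depth: int = 3
    branching: int = 2
    markers_per_edge: int = 2
    founder_length: int = 200
    leaves_per_haplogroup: int = 3
    root_label: str = "MH"
    seed: int = 0

    def __post_init__(self) -> None:
        n_edges = sum(self.branching**d for d in range(1, self.depth + 1))
        if n_edges * self.markers_per_edge > self.founder_length:
            raise SpecError(
                "marker count exceeds founder sequence length: "
                f"{n_edges * self.markers_per_edge} > {self.founder_length}"
            )


def generate_ds_population(
    n: int,
    pi: tuple[float, float] = (0.46, 0.54),
    mu: tuple[float, float] = (0.25, 0.75),
    sigma: tuple[float, float] = (0.07, 0.08),
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` disease scores from a two-component normal mixture,
    truncated to [0,1] by resampling."""
    if abs(sum(pi) - 1.0) > 1e-9 or any(p <= 0 for p in pi):
        raise SpecError("mixture proportions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    components = rng.choice(2, size=n, p=list(pi))
    values = rng.normal(np.take(mu, components), np.take(sigma, components))
    out_of_range = (values < 0) | (values > 1)
    while np.any(out_of_range):
        redraw = rng.normal(
            np.take(mu, components[out_of_range]),
            np.take(sigma, components[out_of_range]),
        )
        values[out_of_range] = redraw
        out_of_range = (values < 0) | (values > 1)
    return values


def generate_nv_values(n: int, scale: float = 0.004, seed: int = 0) -> np.ndarray:
    """Right-skewed background nucleotide variability (exponential).

    With the default scale roughly a quarter of the mass falls below the
    canonical cutoff region (~0.0026 sits near the first quartile of
    Exp(0.004)), so deriving a third-quartile cutoff on mixed populations is
    a meaningful exercise.
    """
    rng = np.random.default_rng(seed)
    return rng.exponential(scale, size=n)


def _random_coding_position(rng: np.random.Generator) -> int:
    gene = GENE_MAP[rng.integers(len(GENE_MAP))]
    return int(rng.integers(gene.start, gene.end + 1))


def generate_cohort(
    spec: CohortSpec, thresholds: Thresholds | None = None
) -> tuple[dict[str, VariantTable], dict[str, set[tuple]]]:
    """Per-sample annotated tables plus the truth record of planted keys.

    Background variants are constructed to fail the cascade: those whose
    sampled DS clears the DST are forced to NV above the NVC, and a slice
    of them additionally fails the reference or haplogroup step.  Planted
    variants always pass every step.  Returns ``(tables, truth)`` with
    ``truth[sample_id]`` the set of planted variant keys for that sample.
    """
    thresholds = thresholds or Thresholds()
    rng = np.random.default_rng(spec.seed)
    all_refs = frozenset(REFERENCE_NAMES)
    tables: dict[str, VariantTable] = {}
    truth: dict[str, set[tuple]] = {}

    planted_by_sample: dict[str, list[PlantedVariant]] = {}
    sample_ids = [f"S{i:03d}" for i in range(spec.n_samples)]
    for pv in spec.planted_pathogenic:
        target = pv.sample_id or sample_ids[0]
        planted_by_sample.setdefault(target, []).append(pv)

    for sample_id in sample_ids:
        rows: list[AnnotatedVariant] = []
        planted = planted_by_sample.get(sample_id, [])
        used_positions = {pv.variant.pos.pos for pv in planted}
        ds_draws = generate_ds_population(
            spec.n_background_variants, spec.ds_pi, spec.ds_mu, spec.ds_sigma,
            seed=int(rng.integers(2**31)),
        )
        nv_draws = generate_nv_values(
            spec.n_background_variants, spec.nv_scale, seed=int(rng.integers(2**31))
        )
        for ds, nv in zip(ds_draws, nv_draws):
            pos = _random_coding_position(rng)
            while pos in used_positions:
                pos = _random_coding_position(rng)
            used_positions.add(pos)
            if ds >= thresholds.dst and nv <= thresholds.nvc:
                # force a failure on the variability step
                nv = thresholds.nvc + float(rng.exponential(spec.nv_scale)) + 1e-6
            fate = rng.random()
            recognized = all_refs if fate > 0.10 else frozenset({"rCRS", "RSRS"})
            hg_defining = bool(0.10 < fate <= 0.20)
            rows.append(
                AnnotatedVariant(
                    variant=Variant(MtPosition(pos), str(rng.choice(list(NUCLEOTIDES)))),
                    coding_effect=CodingEffect.NON_SYNONYMOUS,
                    nt_variability=float(nv),
                    disease_score=float(ds),
                    hf=float(rng.uniform(0.2, 1.0)),
                    recognized_by=recognized,
                    haplogroup_defining=hg_defining,
                    sample_id=sample_id,
                )
            )
        for pv in planted:
            rows.append(
                AnnotatedVariant(
                    variant=pv.variant,
                    coding_effect=CodingEffect.NON_SYNONYMOUS,
                    nt_variability=pv.nt_variability,
                    disease_score=pv.disease_score,
                    hf=pv.hf,
                    recognized_by=all_refs,
                    haplogroup_defining=False,
                    sample_id=sample_id,
                )
            )
        order = rng.permutation(len(rows))
        tables[sample_id] = VariantTable(
            rows=[rows[i] for i in order], provenance=f"synthetic:{sample_id}"
        )
        truth[sample_id] = {pv.variant.key for pv in planted}
    return tables, truth


# ---------------------------------------------------------------------------
# Haplogroup trees and alignments

def _child_labels(parent: str, branching: int) -> list[str]:
    return [f"{parent}{i + 1}" for i in range(branching)]


def generate_marker_tree_and_alignment(
    spec: TreeSpec,
) -> tuple[MarkerTable, MultipleSeqAlignment, dict[str, str], dict[str, str]]:
    """Founder sequence mutated along tree edges by per-edge markers.

    Returns (marker table, leaf alignment, leaf-id -> haplogroup map,
    node -> sequence map).  Leaf records are named ``<id>|<haplogroup>`` so
    the haplogroup survives a FASTA round trip; the node sequences are the
    ground truth for group-wise consensus recovery.
    """
    rng = np.random.default_rng(spec.seed)
    founder = "".join(rng.choice(list(NUCLEOTIDES), size=spec.founder_length))
    table = MarkerTable()
    table.add(spec.root_label, None, [])
    sequences = {spec.root_label: founder}
    available = list(range(1, spec.founder_length + 1))
    rng.shuffle(available)

    frontier = [spec.root_label]
    for _ in range(spec.depth):
        next_frontier = []
        for parent in frontier:
            for child in _child_labels(parent, spec.branching):
                markers: list[Variant] = []
                seq = list(sequences[parent])
                for _ in range(spec.markers_per_edge):
                    pos = available.pop()
                    ref = seq[pos - 1]
                    alt = rng.choice([b for b in NUCLEOTIDES if b != ref])
                    seq[pos - 1] = alt
                    markers.append(Variant(MtPosition(pos), str(alt), ref=ref))
                sequences[child] = "".join(seq)
                table.add(child, parent, markers)
                next_frontier.append(child)
        frontier = next_frontier

    records = []
    leaf_haplogroups: dict[str, str] = {}
    for leaf in frontier:
        for i in range(spec.leaves_per_haplogroup):
            leaf_id = f"g{leaf}_{i}"
            records.append(
                SeqRecord(Seq(sequences[leaf]), id=f"{leaf_id}|{leaf}", description="")
            )
            records[-1].annotations["haplogroup"] = leaf
            leaf_haplogroups[leaf_id] = leaf
    return table, MultipleSeqAlignment(records), leaf_haplogroups, sequences


def synthetic_reference(
    length: int = MT_GENOME_LENGTH, seed: int = 0, n_differences: int = 0
) -> str | tuple[str, ...]:
    """A random synthetic mtDNA-sized reference sequence (NOT the real rCRS;
    bases are uniform random, only the coordinate frame is genuine).

    With ``n_differences > 0``, returns a trio of references (rCRS-like,
    RSRS-like, MHCS-like) where the second and third each differ from the
    first at ``n_differences`` random positions — handy for exercising the
    reference-concordance step.
    """
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list(NUCLEOTIDES), size=length))
    if n_differences == 0:
        return base
    variants = []
    for _ in range(2):
        seq = list(base)
        for pos in rng.choice(length, size=n_differences, replace=False):
            seq[pos] = rng.choice([b for b in NUCLEOTIDES if b != seq[pos]])
        variants.append("".join(seq))
    return (base, *variants)
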