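"""Cascade steps, coding-effect classification, pair comparison, Wilson CIs."""

import numpy as np
import pytest

from mtprior.core import (
    AnnotatedVariant,
    CodingEffect,
    GENE_MAP,
    MtPosition,
    MtPriorError,
    Thresholds,
    Variant,
    VariantKind,
    mito_translate,
    reverse_complement,
)
from mtprior.io_tables import MarkerTable, VariantTable, load_fixture
from mtprior.prioritizer import (
    CascadeFlags,
    ReferenceMismatchError,
    StepMode,
    classify_coding_effect,
    compare_pair,
    distinct_variants,
    flag_haplogroup_defining,
    hf_confidence_interval,
    prioritize,
    recognize_against_references,
)
from mtprior.synthdata import TreeSpec, generate_marker_tree_and_alignment, synthetic_reference


def row(pos, alt="A", **kwargs):
    defaults = dict(
        coding_effect=CodingEffect.NON_SYNONYMOUS,
        nt_variability=0.0005,
        disease_score=0.8,
    )
    defaults.update(kwargs)
    return AnnotatedVariant(variant=Variant(MtPosition(pos), alt), **defaults)


class TestRecognizeAgainstReferences:
    def test_allele_equal_to_all_references_unrecognized(self):
        rcrs = rsrs = mhcs = "ACGTACGTAC"
        sets = recognize_against_references(
            [Variant(MtPosition(3), "G")], rcrs, rsrs, mhcs
        )
        assert sets == [frozenset()]

    def test_haplogroup_fixed_allele_matches_mhcs_only(self):
        rcrs, rsrs, mhcs = "ACGTACGTAC", "ACGTACGTAC", "ATGTACGTAC"
        sets = recognize_against_references(
            [Variant(MtPosition(2), "T")], rcrs, rsrs, mhcs
        )
        assert sets == [frozenset({"rCRS", "RSRS"})]  # not a change vs MHCS

    def test_planted_differences_match_set_intersection_oracle(self, rng):
        rcrs, rsrs, mhcs = synthetic_reference(length=60, seed=13, n_differences=5)
        variants = []
        for pos in range(1, 61):
            current = {rcrs[pos - 1], rsrs[pos - 1], mhcs[pos - 1]}
            alts = [b for b in "ACGT" if b not in current] or ["A"]
            alt = alts[0]
            if alt != rcrs[pos - 1]:
                variants.append(Variant(MtPosition(pos), alt))
        sets = recognize_against_references(variants, rcrs, rsrs, mhcs)
        for v, got in zip(variants, sets):
            expected = {
                name for name, seq in
                (("rCRS", rcrs), ("RSRS", rsrs), ("MHCS", mhcs))
                if seq[v.pos.pos - 1] != v.alt
            }
            assert got == expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ReferenceMismatchError):
            recognize_against_references([], "ACGT", "ACG", "ACGT")


class TestFlagHaplogroupDefining:
    def test_empty_marker_table_flags_nothing(self):
        variants = [Variant(MtPosition(100), "A")]
        assert flag_haplogroup_defining(variants, MarkerTable(), "H1") == [False]

    def test_marker_on_path_is_flagged(self):
        table = MarkerTable()
        table.add("L", None, [])
        table.add("M10", "L", [Variant(MtPosition(14337), "T", ref="C")])
        table.add("M10a1a1", "M10", [Variant(MtPosition(100), "G", ref="A")])
        variants = [
            Variant(MtPosition(14337), "T"),  # on path (ancestor edge)
            Variant(MtPosition(100), "G"),    # on path (own edge)
            Variant(MtPosition(14337), "G"),  # same site, different allele
            Variant(MtPosition(999), "C"),    # not a marker
        ]
        assert flag_haplogroup_defining(variants, table, "M10a1a1") == \
            [True, True, False, False]

    def test_synthetic_tree_matches_path_union_oracle(self):
        spec = TreeSpec(depth=3, branching=2, markers_per_edge=2,
                        founder_length=120, seed=23)
        table, _, leaf_haplogroups, _ = generate_marker_tree_and_alignment(spec)
        all_markers = [v for ms in table.markers.values() for v in ms]
        for haplogroup in set(leaf_haplogroups.values()):
            flags = flag_haplogroup_defining(all_markers, table, haplogroup)
            # oracle: enumerate the path by string-prefix structure of labels
            path = {haplogroup[: len(spec.root_label) + d]
                    for d in range(spec.depth + 1)}
            expected = [
                any(v.key in {m.key for m in table.markers[node]} for node in path)
                for v in all_markers
            ]
            assert flags == expected

    def test_unknown_haplogroup_lists_near_matches(self):
        table = MarkerTable()
        table.add("B4d1", None, [])
        with pytest.raises(MtPriorError, match="B4d1"):
            flag_haplogroup_defining([], table, "B4d2")


@pytest.fixture(scope="module")
def reference():
    return synthetic_reference(seed=99)


class TestClassifyCodingEffect:
    def test_noncoding_position(self, reference):
        effect, aa = classify_coding_effect(Variant(MtPosition(200), "A"), reference)
        assert effect == CodingEffect.NONCODING and aa == ""

    def test_substitutions_match_bruteforce_translation(self, reference):
        """Against an independent oracle that rebuilds and translates whole
        codons from scratch for plus- and minus-strand genes."""
        rng = np.random.default_rng(5)
        genes = {g.name: g for g in GENE_MAP}
        for gene in (genes["MT-ND4"], genes["MT-ND6"], genes["MT-ATP8"]):
            for pos in rng.integers(gene.start, gene.end + 1, size=40):
                pos = int(pos)
                if len([g for g in GENE_MAP if pos in g]) > 1:
                    continue  # overlap convention tested separately
                ref_base = reference[pos - 1]
                alt = next(b for b in "ACGT" if b != ref_base)
                effect, aa = classify_coding_effect(
                    Variant(MtPosition(pos), alt, ref=ref_base), reference
                )
                # oracle
                if gene.strand == "+":
                    off = pos - gene.start
                    idx = off // 3
                    codon_start = gene.start - 1 + idx * 3
                    codon = (reference[codon_start:codon_start + 3] + "AAA")[:3]
                    mutated = list(codon)
                    mutated[off % 3] = alt
                else:
                    off = gene.end - pos
                    idx = off // 3
                    end = gene.end - idx * 3
                    codon = reverse_complement(reference[max(end - 3, 0):end])
                    codon = (codon + "AAA")[:3]
                    mutated = list(codon)
                    mutated[off % 3] = reverse_complement(alt)
                ref_aa = mito_translate(codon)
                alt_aa = mito_translate("".join(mutated))
                if ref_aa == alt_aa:
                    expected = CodingEffect.SYNONYMOUS
                elif alt_aa == "*":
                    expected = CodingEffect.PREMATURE_STOP
                else:
                    expected = CodingEffect.NON_SYNONYMOUS
                assert effect == expected, (gene.name, pos)
                assert aa == f"{ref_aa}{idx + 1}{alt_aa}"

    def test_constructed_synonymous_third_position(self, reference):
        # find a wobble substitution preserving the amino acid
        gene = next(g for g in GENE_MAP if g.name == "MT-CO1")
        for idx in range((gene.length // 3) - 1):
            codon_start = gene.start - 1 + idx * 3
            codon = reference[codon_start:codon_start + 3]
            for alt in "ACGT":
                if alt == codon[2]:
                    continue
                if mito_translate(codon) == mito_translate(codon[:2] + alt):
                    pos = codon_start + 3
                    effect, _ = classify_coding_effect(
                        Variant(MtPosition(pos), alt, ref=codon[2]), reference
                    )
                    assert effect == CodingEffect.SYNONYMOUS
                    return
        pytest.fail("no synonymous wobble substitution found")

    def test_frameshift_and_inframe_indels(self, reference):
        ins1 = Variant(MtPosition(6691), "A", kind=VariantKind.INSERTION)
        assert classify_coding_effect(ins1, reference)[0] == CodingEffect.FRAMESHIFT
        ins3 = Variant(MtPosition(6691), "ACT", kind=VariantKind.INSERTION)
        assert classify_coding_effect(ins3, reference)[0] == \
            CodingEffect.NON_SYNONYMOUS

    def test_reference_mismatch_detected(self, reference):
        pos = 11778
        ref_base = reference[pos - 1]
        wrong = next(b for b in "ACGT" if b != ref_base)
        alt = next(b for b in "ACGT" if b not in (ref_base, wrong))
        with pytest.raises(ReferenceMismatchError):
            classify_coding_effect(
                Variant(MtPosition(pos), alt, ref=wrong), reference
            )


class TestCascade:
    def test_empty_table_gives_zero_counts(self):
        trace = prioritize(VariantTable([]), Thresholds(hf_cutoff=0.5))
        assert trace.prioritized == []
        assert all(count == 0 for _, _, count in trace.steps)

    def test_counts_monotone_nonincreasing(self):
        table = load_fixture("table3")
        trace = prioritize(table, Thresholds(hf_cutoff=0.5))
        counts = [len(table)] + [c for _, _, c in trace.steps]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_idempotent_on_own_output(self):
        thresholds = Thresholds(hf_cutoff=0.5)
        table = load_fixture("table3")
        trace = prioritize(table, thresholds)
        again = prioritize(VariantTable(trace.prioritized), thresholds)
        assert {r.key for r in again.prioritized} == \
            {r.key for r in trace.prioritized}

    def test_nv_and_ds_filters_commute(self):
        rows = [
            row(3307, nt_variability=nv, disease_score=ds)
            for nv, ds in [(0.001, 0.8), (0.01, 0.8), (0.001, 0.1), (0.01, 0.1)]
        ]
        for i, r in enumerate(rows):
            rows[i] = AnnotatedVariant(
                variant=Variant(MtPosition(3307 + i), "A"),
                coding_effect=r.coding_effect, nt_variability=r.nt_variability,
                disease_score=r.disease_score,
            )
        base = prioritize(VariantTable(rows))
        only_ds = prioritize(
            VariantTable(rows), flags=CascadeFlags(variability=StepMode.OFF)
        )
        only_nv = prioritize(
            VariantTable(rows), flags=CascadeFlags(disease_score=StepMode.OFF)
        )
        recombined = {r.key for r in only_ds.prioritized} & \
            {r.key for r in only_nv.prioritized}
        assert {r.key for r in base.prioritized} == recombined

    def test_disabling_haplogroup_step_only_adds(self):
        rows = [
            row(100 + i, haplogroup_defining=(i % 3 == 0), recognized_by=
                frozenset({"rCRS", "RSRS", "MHCS"}))
            for i in range(9)
        ]
        with_filter = prioritize(VariantTable(rows))
        without = prioritize(
            VariantTable(rows), flags=CascadeFlags(haplogroup=StepMode.OFF)
        )
        assert {r.key for r in with_filter.prioritized} <= \
            {r.key for r in without.prioritized}

    def test_stop_and_frameshift_bypass_ds_but_not_other_steps(self):
        stop_ok = row(4810, coding_effect=CodingEffect.PREMATURE_STOP,
                      disease_score=None)
        stop_high_nv = row(4811, coding_effect=CodingEffect.PREMATURE_STOP,
                           disease_score=None, nt_variability=0.5)
        trace = prioritize(VariantTable([stop_ok, stop_high_nv]))
        assert {r.key for r in trace.prioritized} == {stop_ok.key}
        no_bypass = prioritize(
            VariantTable([stop_ok]), flags=CascadeFlags(stop_bypass=False)
        )
        assert no_bypass.prioritized == []

    def test_hf_requires_every_tissue_to_clear_cutoff(self):
        both_high = row(100, hf=(0.9, 0.85))
        one_low = row(101, hf=(0.9, 0.5))
        trace = prioritize(
            VariantTable([both_high, one_low]), Thresholds(hf_cutoff=0.8)
        )
        assert {r.key for r in trace.prioritized} == {both_high.key}

    def test_missing_hf_policy(self):
        no_hf = row(100, hf=None)
        with_hf = row(101, hf=0.9)
        strict = prioritize(VariantTable([no_hf, with_hf]), Thresholds(hf_cutoff=0.5))
        assert {r.key for r in strict.prioritized} == {with_hf.key}
        lenient = prioritize(
            VariantTable([no_hf, with_hf]), Thresholds(hf_cutoff=0.5),
            CascadeFlags(missing_hf_passes=True),
        )
        assert len(lenient.prioritized) == 2

    def test_ci_aware_hf_mode_passes_borderline_with_counts(self):
        borderline = row(100, hf=0.768,
                         annotations={"alt_count": "768", "depth": "1000"})
        strict = prioritize(VariantTable([borderline]), Thresholds(hf_cutoff=0.8))
        assert strict.prioritized == []
        ci_aware = prioritize(
            VariantTable([borderline]), Thresholds(hf_cutoff=0.8),
            CascadeFlags(hf_mode="ci"),
        )
        # Wilson upper bound of 768/1000 is ~0.794 < 0.8: still fails
        assert ci_aware.prioritized == []
        closer = row(101, hf=0.79,
                     annotations={"alt_count": "79", "depth": "100"})
        assert prioritize(
            VariantTable([closer]), Thresholds(hf_cutoff=0.8),
            CascadeFlags(hf_mode="ci"),
        ).prioritized != []

    def test_forced_step_without_data_is_an_error(self):
        with pytest.raises(MtPriorError, match="reference"):
            prioritize(
                VariantTable([row(100)]),
                flags=CascadeFlags(reference=StepMode.ON),
            )

    def test_distinct_variants_counts_recurrent_once(self):
        table = load_fixture("table4")
        ns_rows = [r for r in table.rows
                   if r.coding_effect == CodingEffect.NON_SYNONYMOUS]
        assert len(ns_rows) == 23
        assert len(distinct_variants(ns_rows)) == 21  # m.3380G>A in 3 samples


class TestComparePair:
    def test_identical_tables_all_germline(self):
        rows = [row(100), row(200, alt="C")]
        result = compare_pair(VariantTable(rows), VariantTable(list(rows)))
        assert result.tumor_specific == [] and result.normal_specific == []
        assert len(result.germline) == 2

    def test_disjoint_tables_all_specific(self):
        result = compare_pair(
            VariantTable([row(100)]), VariantTable([row(200, alt="C")])
        )
        assert len(result.tumor_specific) == 1
        assert len(result.normal_specific) == 1
        assert result.germline == []

    def test_random_pairs_match_set_algebra_oracle(self, rng):
        for _ in range(100):
            t_keys = set(map(int, rng.choice(500, size=rng.integers(1, 20),
                                             replace=False)))
            n_keys = set(map(int, rng.choice(500, size=rng.integers(1, 20),
                                             replace=False)))
            tumor = VariantTable([row(1000 + k) for k in sorted(t_keys)])
            normal = VariantTable([row(1000 + k) for k in sorted(n_keys)])
            result = compare_pair(tumor, normal)
            ts = {r.key[0] - 1000 for r in result.tumor_specific}
            ns = {r.key[0] - 1000 for r in result.normal_specific}
            gl = {t.key[0] - 1000 for t, _ in result.germline}
            assert ts == t_keys - n_keys
            assert ns == n_keys - t_keys
            assert gl == t_keys & n_keys
            assert ts.isdisjoint(gl) and ns.isdisjoint(gl)

    def test_duplicate_key_rejected_naming_it(self):
        rows = [row(100), row(100)]
        with pytest.raises(MtPriorError, match="100"):
            compare_pair(VariantTable(rows), VariantTable([]))

    def test_ci_overlap_rule_flags_discordant_shared_variants(self):
        tumor = VariantTable([row(100, hf=0.9,
                                  annotations={"alt_count": "90", "depth": "100"})])
        normal = VariantTable([row(100, hf=0.2,
                                   annotations={"alt_count": "20", "depth": "100"})])
        result = compare_pair(tumor, normal, ci_rule="overlap")
        assert len(result.germline) == 1
        assert result.ci_discordant == {tumor.rows[0].key}


class TestWilsonInterval:
    def test_boundary_cases(self):
        low, _ = hf_confidence_interval(0, 10)
        _, high = hf_confidence_interval(10, 10)
        assert low == pytest.approx(0.0, abs=1e-12)
        assert high == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula(self):
        from scipy.stats import norm

        alt, depth, level = 80, 100, 0.95
        z = norm.ppf(1 - (1 - level) / 2)
        p = alt / depth
        denom = 1 + z**2 / depth
        centre = (p + z**2 / (2 * depth)) / denom
        half = z * np.sqrt(p * (1 - p) / depth + z**2 / (4 * depth**2)) / denom
        low, high = hf_confidence_interval(alt, depth, level)
        assert low == pytest.approx(centre - half)
        assert high == pytest.approx(centre + half)

    def test_random_counts_match_formula(self, rng):
        from scipy.stats import norm

        z = norm.ppf(0.975)
        for _ in range(50):
            depth = int(rng.integers(1, 500))
            alt = int(rng.integers(0, depth + 1))
            p = alt / depth
            denom = 1 + z**2 / depth
            centre = (p + z**2 / (2 * depth)) / denom
            half = z * np.sqrt(p * (1 - p) / depth + z**2 / (4 * depth**2)) / denom
            low, high = hf_confidence_interval(alt, depth)
            assert low == pytest.approx(centre - half, abs=1e-10)
            assert high == pytest.approx(centre + half, abs=1e-10)

    def test_zero_depth_rejected(self):
        with pytest.raises(MtPriorError):
            hf_confidence_interval(0, 0)
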