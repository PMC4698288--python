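"""Partition tumor and matched-normal variants by somatic status.

Compares two variant tables from the same individual keyed by (position,
allele): variants private to the tumor are candidate somatic events,
shared ones are germline.  With read counts available, Wilson 95%
intervals on the heteroplasmic fraction support a CI-overlap check on
germline calls.
"""

from mtprior import AnnotatedVariant, MtPosition, Variant, VariantTable, compare_pair

def row(pos, alt, hf, alt_count, depth):
    return AnnotatedVariant(
        variant=Variant(MtPosition(pos), alt), hf=hf,
        annotations={"alt_count": str(alt_count), "depth": str(depth)},
    )

tumor = VariantTable([
    row(3460, "A", 0.95, 190, 200),
    row(11778, "A", 0.90, 180, 200),
    row(14484, "C", 0.60, 120, 200),   # tumor-only
])
normal = VariantTable([
    row(3460, "A", 0.97, 145, 150),
    row(11778, "A", 0.20, 30, 150),    # shared but very different HF
])

result = compare_pair(tumor, normal, ci_rule="overlap")
print(f"tumor-specific: {[str(r.variant) for r in result.tumor_specific]}")
print(f"germline:       {[str(t.variant) for t, _ in result.germline]}")
print(f"normal-specific:{[str(r.variant) for r in result.normal_specific]}")
for key, cis in sorted(result.hf_ci.items()):
    note = "CI discordant" if key in result.ci_discordant else "CI overlap"
    spans = {k: f"[{lo:.3f},{hi:.3f}]" for k, (lo, hi) in cis.items()}
    print(f"  m.{key[0]}: {spans}  -> {note}")
# m.14484T>C is the somatic candidate; m.11778's HF intervals do not
# overlap between tissues, flagging the germline call for review.
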