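"""Run the prioritization cascade on the packaged ovarian-cancer table.

The table lists candidate variants from 20 ovarian carcinoma genomes with
their nucleotide variability (NV), ensemble disease score (DS) and
heteroplasmic fraction (HF).  The cascade keeps variants with NV <= 0.0026,
protein-changing effect, DS >= 0.4311 (truncating variants bypass the
score) and HF >= 0.5.
"""

from mtprior import Thresholds, load_fixture, prioritize

table = load_fixture("table3")
trace = prioritize(table, Thresholds(hf_cutoff=0.5))

print(f"input rows: {len(table)}")
for name, _, count in trace.steps:
    print(f"step {name:<13} surviving {count}")
print("prioritized candidates:")
for row in trace.prioritized:
    ds = f"{row.disease_score:.4f}" if row.disease_score is not None else "  --  "
    print(f"  {str(row.variant):>10}  {row.locus:<8} DS={ds} "
          f"HF={row.hf}  {row.aa_change}")
# Each surviving row is a candidate somatic variant likely to affect
# protein function; the frameshift carries no DS but is kept by design.
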