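"""Find SSR motifs in contigs and screen primer pairs against design windows.

The scanner reports maximal perfect tandem repeats (unit 1-6 nt, per-unit
minimum repeat counts); the primer screen applies length 18-23 nt, product
100-280 bp, Tm 54-60 C and pair Tm difference <= 0.5 C, using a GC-fraction
Tm approximation.
"""

from weevilpop.marker_discovery import evaluate_primer_pair, scan_ssr_motifs
from weevilpop.synthetic_data import make_contig_fixtures

records, truth = make_contig_fixtures(
    4,
    planted=[("AAC", 6, (80, 80)), ("T", 10, (75, 75)), ("CTGCA", 4, (70, 70))],
    seed=5,
)
for name, seq in records:
    for hit in scan_ssr_motifs(seq, contig=name):
        print(f"{hit.contig}: ({hit.motif}){hit.repeats} at {hit.start}-{hit.end}, "
              f"flanks {hit.left_flank}/{hit.right_flank} bp")
print("(the fourth contig is repeat-free background, so it prints nothing)")

assessment = evaluate_primer_pair(
    forward="GCGCGCGCGCGCATATATAT",
    reverse="GCGCGCGCGCGCTATATATA",
    product_length=180,
)
print(f"\nprimer pair Tm {assessment.tm_forward:.2f}/{assessment.tm_reverse:.2f} C,"
      f" delta {assessment.tm_delta:.2f} C -> {assessment.verdict}")

bad = evaluate_primer_pair("GCCTATAATAGACCGTTTGG", "GTGAAGAACATTGTAACATCTC", 130)
print(f"AT-rich pair -> {bad.verdict}: {'; '.join(bad.violations)}")
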