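"""Classify the TP53 LOH state from allele-specific copy number and decide
which physical allele (mutant vs wildtype) was gained from the VAF shift."""

from lohtime import CnSegment, assign_mutant_allele, classify_locus, vaf_shift_test

CHR17 = 81_195_210
TP53 = ("17", 7_565_096, 7_590_856)  # 0-based half-open

# whole-chromosome 2+0: both copies are the same parental allele
segments = [CnSegment("17", 0, CHR17, major=2, minor=0)]
call = classify_locus(segments, TP53, CHR17)
print(f"LOH state  = {call.state.value} ({call.extent.value})")
print(f"copies     = {call.mutant_copies} mutant / {call.wildtype_copies} wildtype")

# germline variant at ~50% in blood rises toward 85% in a 70%-pure tumor
# when the mutant-bearing chromosome is the one that was duplicated
p = vaf_shift_test(germ_alt=20, germ_depth=40, tum_alt=50, tum_depth=60)
assignment = assign_mutant_allele(
    germline_vaf=0.5, tumor_alt=50, tumor_depth=60, purity=0.7, major=2, minor=0
)
print(f"tumor-vs-germline VAF shift: Fisher p = {p:.2e}")
print(f"mutant allele sits on the {assignment.allele} allele")
print(f"expected VAF if mutant on major = {assignment.expected_vaf['MAJOR']:.3f}, "
      f"on minor = {assignment.expected_vaf['MINOR']:.3f}")
# CN_LOH + mutant-on-major means the tumor duplicated the mutant TP53
# chromosome and lost the wildtype one.
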