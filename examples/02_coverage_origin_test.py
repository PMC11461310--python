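"""The coverage-differential origin test on reported depth figures.

A symbiont region showing 829X mean depth between host flanks at 15,244X
and 18,099X is ~20-fold under-covered relative to its host — depth the
region could not have if it were a genuine chromosomal integration (HGT),
which would travel with the host at host depth.
"""

from endomine.coverage import coverage_ratio, verdict_from_ratio

flanks = (15_244.0, 18_099.0)
region = 829.0
r = coverage_ratio(region, flanks)
print(f"flank means: {flanks[0]:,.0f}X and {flanks[1]:,.0f}X")
print(f"symbiont region mean: {region:,.0f}X")
print(f"R = {region:.0f} / mean{flanks} = {r:.4f}")
for gap_flanked in (True, False):
    verdict = verdict_from_ratio(r, gap_flanked=gap_flanked)
    print(f"gap-flanked junctions: {gap_flanked!s:5} -> {verdict}")
# With junction N-gaps the extreme ratio reads ENDOSYMBIONT; without the
# gap evidence the same ratio alone stays AMBIGUOUS.
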