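"""Close a circular genome from a linear region plus junction-spanning reads.

Reads anchored at the region's downstream terminus vote a consensus
extension; when the extension runs past the circular origin it duplicates
the region start, and trimming one copy of that terminal overlap yields
the circle.  Rotation is canonicalized so assemblies compare as strings.
"""

import numpy as np

from endomine.circularize import (canonical_rotation, circularize,
                                  detect_terminal_overlap, gap_fill, is_rotation)

rng = np.random.default_rng(0)
circle = "".join("ACGT"[i] for i in rng.integers(0, 4, 8_000))

# the assembly kept only the first 7,738 bp; the last 262 bp were lost
region = circle[:-262]
# five reads crossing the junction: end of the region, the missing 262 bp,
# and a bit of the region start again
reads = [circle[-1_000:] + circle[:400] for _ in range(5)]

ext = gap_fill(region, reads)
print(f"consensus extension: {len(ext.sequence)} bp from {ext.supporting_reads} reads")
extended = region + ext.sequence
overlap = detect_terminal_overlap(extended)
print(f"terminal overlap: {overlap.length} bp at {overlap.identity:.1f}% identity")
genome = canonical_rotation(circularize(extended, overlap))
print(f"closed circle: {len(genome.sequence):,} bp "
      f"(merged {genome.merged_overlap} bp, rotation offset {genome.rotation_offset})")
print("matches the original circle exactly:", is_rotation(genome.sequence, circle))
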