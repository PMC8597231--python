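"""Score a soft-clipped read against its spliced realignment.

The refinement scorer awards +1 per aligned base, -1 per gap open, -1 per
gap-extend unit, and +5 per splice shorter than 100 kb; a realignment
replaces the original only when the improvement rules say so.
"""

from editarm.refinement import (RefinementCandidate, is_improvement,
                                score_alignment, simple_spliced_realign)
from editarm.records import AlignmentRecord
import numpy as np

rng = np.random.default_rng(0)
window = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
read = window[300:350] + window[1150:1201]      # spans an 800 bp intron

clipped_ops = [("M", 50), ("S", 51)]            # what phase 1 kept
cand = simple_spliced_realign(read, window)

print(f"original (soft-clipped) score: {score_alignment(clipped_ops)}")
print(f"realigned ops:                 {cand.alignment.ops}")
print(f"realigned score:               {cand.score}")
orig = RefinementCandidate(
    AlignmentRecord(read_id="r", mapped=True, chrom="w", pos=300,
                    ops=clipped_ops, seq=read),
    score_alignment(clipped_ops))
print(f"improvement accepted:          {is_improvement(orig, cand)}")
# 101 aligned bases + 5 splice bonus = 106, beating the 50 of the clipped
# alignment, so the spliced placement replaces it.
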