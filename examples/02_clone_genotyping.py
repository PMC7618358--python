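"""Genotype clonal cell lines from junction reads.

A clone with one integration shows junction reads from both ITR sides at a
single location; a hopping-induced deletion leaves the 5' ITR at the launch
site and the 3' ITR at the re-integration site, so two single-sided
locations appear and the interval between them has been lost.
"""

import pandas as pd

from hoplandscape.calling import call_clone, infer_deletion_interval


def reads_from(spec):
    rows, frag = [], 0
    for pos, n5, n3 in spec:
        for _ in range(n5):
            frag += 1
            rows.append(("chr3", pos, "+", "ITR5", 30, frag))
        for _ in range(n3):
            frag += 1
            rows.append(("chr3", pos, "-", "ITR3", 30, frag))
    return pd.DataFrame(rows, columns=["chrom", "position", "orientation",
                                       "itr_side", "mapq", "fragment_end"])


# clone A: one location supported by both ITR sides -> clean insertion
call = call_clone(reads_from([(34_700_000, 30, 25)]))
print(f"clone A verdict: {call.verdict} at position "
      f"{int(call.insertion_site['position'])}")

# clone B: 5' ITR still at the launch pad, 3' ITR 59 kb away -> deletion
call = call_clone(reads_from([(34_641_000, 40, 0), (34_700_000, 0, 35)]))
chrom, start, end, width = infer_deletion_interval(call)
print(f"clone B verdict: {call.verdict}, lost {chrom}:{start}-{end} ({width} bp)")

# clone C: a second strong location (possible index swap) -> manual review
call = call_clone(reads_from([(34_700_000, 30, 25), (34_800_000, 12, 11)]))
print(f"clone C verdict: {call.verdict} ({call.reason})")
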