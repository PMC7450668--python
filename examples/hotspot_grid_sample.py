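"""One cell of the hotspot grid protocol, detected and checked.

The full protocol enumerates 201 duplication lengths x 201 start
positions (40,401 configurations), each a balanced mixture of 1,000
duplication and 1,000 wild-type read pairs.  This example runs a single
configuration and verifies the call against its truth record with the
hotspot matching criterion (left breakpoint in the region, exact size).
"""

from itdscan import MatchCriteria, match_calls, scan_records
from itdscan.simulate import emulate_alignment, run_protocol

proto = run_protocol("hotspot_grid", seed=5)
print(f"grid: {len(proto.configs)} (length, start) configurations")

length, start = 90, 1001  # one cell: a 90-bp duplication
reads, truth = proto.sample_reads(length, start)
records = emulate_alignment(reads, {proto.chrom: proto.reference})
calls = [c for c in scan_records(records, {proto.chrom: proto.reference})
         if c.filter == "PASS"]
for c in calls:
    print(f"call: {c.chrom}:{c.pos} size={c.size} VAF={c.VAF:.3f} [{c.filter}]")

crit = MatchCriteria(mode="hotspot", hotspot_region=(951, 951 + 201 + 201))
counts = match_calls(calls, [truth], crit).counts
print(f"hotspot-mode match: TP={counts.TP} FP={counts.FP} FN={counts.FN}")
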