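"""Encode a protein as its normalised tripeptide composition.

A sequence of length L has L - 2 overlapping 3-residue windows; the
composition vector gives each of the 8000 possible tripeptides its
window frequency, so the vector always sums to 1.
"""

import canlect as cl

record = cl.ProteinRecord("demo", "ACDCACDEFG")
counts, windows = cl.count_tripeptides(record)
vector = cl.composition_vector(record)

print(f"sequence: {record.sequence}  (length {len(record)})")
print(f"windows counted: {windows}")
for trip in ("ACD", "CDC", "DCA", "CAC", "CDE", "DEF", "EFG"):
    i = cl.TRIPEPTIDES[trip]
    print(f"  {trip}: count {counts[i]}, frequency {vector[i]:.3f}")
print(f"vector length: {vector.shape[0]}, sum: {vector.sum():.9f}")
# ACD occurs twice among the 8 windows, so its frequency is 0.25; every
# other observed tripeptide occurs once (0.125), and the 8000-entry
# vector sums to exactly 1.
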