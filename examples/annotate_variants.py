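"""Enumerate and annotate uORF-perturbing variants on a small transcript.

Builds a 16-nt 5'UTR containing a strong-Kozak uORF, enumerates every
uAUG-creating and stop-removing SNV, and annotates a single-base insertion
that frameshifts the existing uORF so it bypasses its stop codon and overlaps
the coding sequence.
"""

from uorfkit import (
    TranscriptRecord,
    TranscriptVariant,
    annotate_variant,
    enumerate_stop_removing_snvs,
    enumerate_uaug_snvs,
    find_uorfs,
)
from uorfkit.annotation import records_to_frame

# UTR "AAGGATGGACTAGCCC": ATG at 4 in a strong Kozak context (-3 = A, +3 = G),
# in-frame TAG stop at 10 -> an existing uORF
t = TranscriptRecord("GENE1", "TX1", "AAGGATGGACTAGCCC", "ATGGCTAAA")

print("Existing upstream ORFs:")
for u in find_uorfs(t):
    kind = "oORF (no UTR stop)" if u.is_oorf else f"uORF, stop at {u.stop_start}"
    print(f"  ATG at {u.start}: {kind}, Kozak {u.start_kozak.value}")

records = enumerate_uaug_snvs(t) + enumerate_stop_removing_snvs(t, find_uorfs(t))
print(f"\nAll possible perturbing SNVs ({len(records)}):")
print(records_to_frame(records).to_string(index=False))

# a 1-bp insertion inside the uORF body shifts its frame: the old stop is
# bypassed and the ORF now runs into the CDS out of frame (high impact)
ins = TranscriptVariant("TX1", 9, "", "T")
print("\nInsertion of T at position 9 (inside the uORF):")
for r in annotate_variant(t, ins):
    print(
        f"  {r.kind}: {r.consequence}, Kozak {r.kozak.value}, "
        f"distance to CDS {r.distance_to_cds} nt, high impact: {r.high_impact}"
    )
print(
    "\nThe frameshifted uORF lost its stop codon and overlaps the CDS"
    " out-of-frame - the variant class most depleted in populations."
)
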