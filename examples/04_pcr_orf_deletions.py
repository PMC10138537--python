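"""In-silico PCR, ORF annotation and deletion-span calls on the reference.

Uses the package's synthetic reference fragment, which reproduces the
marker's published geometry (primer sites, product sizes, an 876-nt coding
sequence). Predicts each primer pair's product, annotates the open reading
frame, and shows how a large-deletion allele is reported in CDS
coordinates.
"""

from ctmarker.marker_tools import STUDY_PRIMERS, find_amplicon, find_orf
from ctmarker.polymorphism import deletion_span
from ctmarker.seq_io import NucSequence
from ctmarker.simulate import synthetic_reference_cds, synthetic_reference_fragment

fragment, geometry = synthetic_reference_fragment()
print(f"reference fragment: {len(fragment)} nt (synthetic stand-in)")

for name, pair in STUDY_PRIMERS.items():
    (hit,) = find_amplicon(fragment, pair)
    print(f"  {name:<8s} product {hit.start}..{hit.end} = {hit.length} nt "
          f"(published size {pair.expected_size})")

orf = find_orf(fragment, min_length=300)[0]
print(f"ORF: {orf.cds_start}..{orf.cds_end} ({orf.coding_length} coding nt, "
      f"{orf.protein_length} aa)")

cds = synthetic_reference_cds()
mutant = NucSequence("deletion_allele", cds.residues[:197] + cds.residues[800:])
span = deletion_span(mutant, cds)
print(f"large-deletion allele: deletion spans CDS {span} "
      "(frame-preserving, like the common swamp-cranberry allele)")
truncated = NucSequence("truncated_allele", cds.residues[:158])
print(f"truncated allele: deletion spans CDS {deletion_span(truncated, cds)}")
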