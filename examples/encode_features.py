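"""Encode one cysteine site into its feature vector.

Builds a small protein by hand, derives a stand-in conservation profile
from BLOSUM62, and shows how the distance / PSSM / secondary-structure
blocks concatenate into a single named vector.
"""

from redoxcys.features import FeatureSpec, encode_site, sequential_distances
from redoxcys.seqio import CysteineSite, ProteinRecord, StructureAnnotation, pseudo_pssm

record = ProteinRecord("demo", "MKCAACWWKLCDERTGHCVI")
site = CysteineSite("demo", 6, label=+1)  # the cysteine at position 6

spec = FeatureSpec(n_neighbors=6, window=9, blocks=("D", "PSSM", "SS"))
annotation = StructureAnnotation("demo", "CCHHHHCCCEEEECCHHHCC")
fv = encode_site(site, spec, record, pssm=pseudo_pssm(record.sequence), annotation=annotation)

print(f"protein {record.id}: {record.sequence}")
print(f"site position {site.position} -> {len(fv.values)} features")
d = sequential_distances(record.sequence, site.position, 6)
print("distance block (residues to the 1st..6th nearest cysteine):", d.astype(int).tolist())
print("first PSSM feature:", fv.names[6], "=", fv.values[6])
print("last SS feature:   ", fv.names[-1], "=", fv.values[-1])
# Distances are raw residue counts; missing neighbours are padded with the
# sequence length (20 here), an unattainable-or-maximal distance.
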