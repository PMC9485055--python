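"""Candidate curation: histidine-box motif filtering and redundancy clustering.

Fatty-acid-desaturase (FAD) family members carry a tripartite histidine-box
motif coordinating the di-iron center.  This example scans a small protein
set with the PROSITE-style pattern, discards non-matching sequences, and
collapses near-identical ones with greedy clustering, mirroring how a
candidate set is curated before phylogenetics.
"""

from fadevo import (
    TRIPARTITE_HISTIDINE_MOTIF,
    ProteinSequence,
    filter_by_motif,
    global_align,
    greedy_cluster,
    parse_pattern,
)

# one true FAD-like sequence (spacers drawn inside the motif's ranges),
# a near-identical copy, and one unrelated protein
fad = ("MSTA" + "H" + "AIL" + "H" + "G" * 12 + "H" + "LV" + "HH"
       + "A" * 80 + "Q" + "ST" + "HH" + "KDEL")
fad_copy = fad[:-1] + "V"          # one substitution
unrelated = "MKV" + "LAGSTDE" * 15

pattern = parse_pattern(TRIPARTITE_HISTIDINE_MOTIF)
proteins = [
    ProteinSequence("des22a_like", fad),
    ProteinSequence("des22a_dup", fad_copy),
    ProteinSequence("other", unrelated),
]

kept, discarded = filter_by_motif(proteins, pattern)
print("motif filter kept:", [p.id for p in kept])
print("motif filter discarded:", [p.id for p in discarded])

clusters = greedy_cluster(kept, threshold=0.99)
print(f"{len(clusters)} cluster(s) at 0.99 identity; representatives:",
      [c.representative.id for c in clusters])

res = global_align(proteins[0], proteins[1])
print(f"pairwise identity {res.identity:.1f}%, similarity {res.similarity:.1f}% "
      f"(alignment length {res.length})")
# identity counts identical aligned pairs; similarity also counts
# positive-scoring BLOSUM62 substitutions.
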