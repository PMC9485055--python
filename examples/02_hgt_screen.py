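"""Parametric HGT screen: is a gene family's codon usage alien to its host?

Two runs of the same screen: a null family drawn from the host-genome
generator (should look native) and an "alien" family with shifted GC3
(a positive control for a horizontally transferred gene set).
"""

from fadevo import genetic_code, hgt_screen, sample_biased_genome

code = genetic_code(1)
background = sample_biased_genome(100, 300, gc3_target=0.25, seed=1,
                                  code=code, id_prefix="host")

for label, gc3 in (("native-like family", 0.25), ("GC3-shifted family", 0.8)):
    family = sample_biased_genome(8, 300, gc3_target=gc3, seed=2,
                                  code=code, id_prefix="fam")
    report = hgt_screen(family, background)
    print(f"--- {label} (GC3 target {gc3}) ---")
    print(f"rank-sum p, ENc:  {report.enc_pvalue:.3g}")
    print(f"rank-sum p, GC3s: {report.gc3s_pvalue:.3g}")
    print(f"verdict: {report.verdict}")
    # A small p says the family's codon usage could not plausibly have been
    # drawn from the host genome's distribution - the parametric signature
    # of horizontal transfer.  A large p is consistent with native origin
    # (as the sterol C-22 desaturase family looks in Tetrahymena).
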