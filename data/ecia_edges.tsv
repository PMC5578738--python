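# Prior interaction network from the earlier plate-based extracellular
# interactome screen (ECIA), transcribed from published network figures.
# Editable reference data, not asserted ground truth.
protein_a	protein_b
Beat-Ia	Side
Beat-Ib	Side
Beat-IIa	Side-IV
Beat-IIb	Side-IV
Beat-Va	Side-VI
Beat-Vb	Side-VI
Beat-Vc	Side-VI
Side-II	Side-III
CG17839	Side-VII
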