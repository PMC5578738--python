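# Family annotation for the 23 screened proteins.
protein	family
Beat-Ia	Beat
Beat-Ib	Beat
Beat-Ic	Beat
Beat-IIa	Beat
Beat-IIb	Beat
Beat-IIIa	Beat
Beat-IIIb	Beat
Beat-IIIc	Beat
Beat-IV	Beat
Beat-Va	Beat
Beat-Vb	Beat
Beat-Vc	Beat
Beat-VI	Beat
Beat-VII	Beat
Side	Side
Side-II	Side
Side-III	Side
Side-IV	Side
Side-V	Side
Side-VI	Side
Side-VII	Side
Side-VIII	Side
CG17839	other
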