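# Synthetic exonic splicing enhancer hexamer set (GA-rich purine class,
# modelled on SELEX/RESCUE-class enhancer vocabularies; not a reproduction of
# any published set). One RNA 6-mer per line.
GAAGAA
AAGAAG
AGAAGA
GAAGGA
GGAAGA
AGGAAG
GAAGAG
GAGAAG
AAGGAA
AGAAGG
GGAGAA
AAGAGG
GAGGAA
AGAGGA
GAAAGA
AGAAAG
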