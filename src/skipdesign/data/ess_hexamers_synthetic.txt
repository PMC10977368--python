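# Synthetic exonic splicing silencer hexamer set (UAG/UGG pyrimidine-purine
# class, modelled on FAS-class silencer vocabularies; not a reproduction of
# any published set). One RNA 6-mer per line.
UAGGGU
UAGGGA
AUAGGG
UAGACU
UAGGUU
UUAGGG
GUAGGU
UAGAGU
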