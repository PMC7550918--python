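site,residue
Site-1,TYR371
Site-1,PHE504
Site-1,VAL509
Site-2,GLN178
Site-2,SER339
Site-2,ARG499
Site-3,TYR341
Site-3,ALA513
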