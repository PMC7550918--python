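compound,pIC50
celecoxib,7.40
polmacoxib,8.57
valdecoxib,8.30
celecoxib-analog,8.10
SC-558,8.03
SC-58125,7.40
rofecoxib,6.30
DuP-697,8.04
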