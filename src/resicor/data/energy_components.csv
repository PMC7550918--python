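compound,vdw_kJmol,elec_kJmol,polar_solv_kJmol,sasa_kJmol,binding_kJmol
celecoxib,-224.66,-134.98,182.56,-20.95,-198.03
polmacoxib,-227.50,-135.45,166.50,-20.16,-216.61
valdecoxib,-223.09,-141.71,158.65,-18.30,-224.45
celecoxib-analog,-267.01,-165.37,183.58,-20.43,-269.24
SC-558,-264.45,-150.19,167.53,-20.66,-267.77
SC-58125,-257.63,-97.15,159.46,-20.57,-215.89
rofecoxib,-236.89,-136.90,167.51,-18.19,-224.48
DuP-697,-265.36,-54.28,109.36,-19.36,-229.64
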