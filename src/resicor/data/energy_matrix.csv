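compound,GLN178,SER339,TYR341,PHE504,ARG499,VAL509,ALA513,VAL335,LEU338,TYR371,ILE503,SER516
celecoxib,-2.78,-4.41,-3.47,-10.22,-7.01,-11.56,-5.78,-4.70,-9.22,-2.18,-5.38,1.86
polmacoxib,-4.06,-5.66,-4.47,-12.88,-6.97,-10.76,-4.29,-5.49,-8.10,-1.21,-5.84,-8.44
valdecoxib,-4.34,-8.08,-4.03,-13.90,-2.82,-10.93,-4.28,-4.89,-9.80,-2.62,-6.38,-5.76
celecoxib-analog,-1.25,-8.51,-5.72,-15.15,-13.00,-13.66,-6.77,-6.07,-10.33,-4.38,-4.39,-0.90
SC-558,-7.09,-6.03,-4.41,-13.76,-7.58,-12.10,-5.41,-6.01,-9.11,-4.00,-6.62,1.22
SC-58125,0.69,-4.81,-2.10,-13.31,-1.95,-13.54,-6.08,-4.15,-10.90,-3.10,-5.36,2.53
rofecoxib,1.15,-3.91,-1.93,-13.23,-3.32,-11.63,-3.76,-6.18,-11.86,-5.43,-8.13,-9.18
DuP-697,-0.02,-4.29,-4.67,-13.46,-1.21,-10.50,-6.35,-5.93,-9.46,-3.19,-7.36,0.87
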