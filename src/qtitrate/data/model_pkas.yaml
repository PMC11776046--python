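# Model-compound pKa values of the titratable groups (free side chains /
# termini in short unstructured peptides). These are configuration data: any
# table with the same keys may be supplied instead via the run configuration.
D: 3.86
E: 4.34
H: 6.54
C: 8.49
Y: 9.76
K: 10.34
NTERM: 7.70
CTERM: 3.67
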