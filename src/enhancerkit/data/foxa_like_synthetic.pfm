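>FOXA_SYN1 synthetic forkhead-like PFM (constructed around a TGTTTAC core; not a database download)
A [ 40 25  5  5  5 10 10 75 10 35 30 25 ]
C [ 15 20  5  5 10  5 10 10 70 10 25 25 ]
G [ 15 25  5 80  5  5 10  5 10 10 20 25 ]
T [ 30 30 85 10 80 80 70 10 10 45 25 25 ]
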