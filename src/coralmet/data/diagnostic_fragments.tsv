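class	fragment_mzs
glycerophosphocholine	86.0968,104.1072,184.0730,240.0991
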