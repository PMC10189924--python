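# Institution alias table: <alias>TAB<canonical>. Edit freely; unknown names pass through.
MSKCC	Memorial Sloan Kettering Cancer Center
Memorial Sloan Kettering	Memorial Sloan Kettering Cancer Center
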