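raw_name	canonical
affymetrix	Affymetrix
affymetrix, inc.	Affymetrix
affymetrix inc.	Affymetrix
affymetrix inc	Affymetrix
affx	Affymetrix
agilent	Agilent
agilent technologies	Agilent
agilent technologies, inc.	Agilent
agilent technologies inc.	Agilent
agilent technologies inc	Agilent
nimblegen	NimbleGen
nimblegen systems	NimbleGen
nimblegen systems, inc.	NimbleGen
nimblegen systems inc.	NimbleGen
nimblegen systems of iceland, llc	NimbleGen
roche nimblegen	NimbleGen
roche nimblegen, inc.	NimbleGen
roche nimblegen inc.	NimbleGen
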