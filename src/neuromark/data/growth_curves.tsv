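sex	age	volume
M	1	340000
M	3	460000
M	5	510000
M	8	555000
M	12	585000
M	16	575000
M	20	560000
M	30	535000
M	40	515000
M	60	480000
M	80	445000
F	1	305000
F	3	410000
F	5	455000
F	8	495000
F	12	520000
F	16	512000
F	20	499000
F	30	476000
F	40	458000
F	60	427000
F	80	396000
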