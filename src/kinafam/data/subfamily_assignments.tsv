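# Published subfamily assignment of the 18 kiwifruit MAPKs (phylogeny with
# 20 Arabidopsis + 14 grapevine references). AcMAPK18 sits in group E despite
# carrying a TDY activation loop.
name	group
AcMAPK1	B
AcMAPK2	C
AcMAPK3	B
AcMAPK4	B
AcMAPK5	A
AcMAPK6	E
AcMAPK7	C
AcMAPK8	B
AcMAPK9	C
AcMAPK10	D
AcMAPK11	B
AcMAPK12	A
AcMAPK13	E
AcMAPK14	D
AcMAPK15	A
AcMAPK16	A
AcMAPK17	D
AcMAPK18	E
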