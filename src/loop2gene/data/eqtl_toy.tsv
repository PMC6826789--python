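gene	variant	p_value
SNX11	rs882380	1.0e-12
SNX11	rs1000001	5.0e-06
HOXB2	rs882380	3.0e-09
HOXB2	rs1000002	1.0e-04
SRP14	rs937213	2.0e-10
SRP14	rs1000003	2.0e-02
BCL11A	rs7579014	4.0e-08
BCL11A	rs1000004	5.0e-01
HNF1B	rs1000005	1.0e-07
HNF1B	rs11651052	1.0e-03
DMXL2	rs1000006	1.0e-02
NOTTARGET1	rs11651052	1.0e-09
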