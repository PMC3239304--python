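# concept1_id	relation	concept2_id
C0012798	treats	C0020615
C0016832	treats	C0010692
C0031469	treats	C0042109
C0025598	treats	C0011849
C0042196	prevents	C0021400
C0042014	diagnoses	C0010692
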