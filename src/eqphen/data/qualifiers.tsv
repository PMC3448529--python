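# APO qualifier composition table: qualifier_id <TAB> strategy <TAB> value
# strategy "substitute": replace the quality atom by the PATO equivalent
# strategy "magnitude": wrap the quality with the magnitude relation against
#   the reference quality normal (PATO:0000461)
APO:0000002	substitute	PATO:0000460
APO:0000003	magnitude	decreased-in-magnitude-relative-to
APO:0000004	magnitude	increased-in-magnitude-relative-to
APO:0000005	substitute	PATO:0000462
APO:0000250	substitute	PATO:0000297
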