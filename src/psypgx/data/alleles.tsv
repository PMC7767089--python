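gene	allele	activity_class
CYP1A2	*1	normal
CYP1A2	*1F	increased_inducibility
CYP2B6	*1	normal
CYP2B6	*6	inactive
CYP2C9	*1	normal
CYP2C9	*2	reduced
CYP2C9	*3	inactive
CYP2C19	*1	normal
CYP2C19	*2	inactive
CYP2C19	*4	inactive
CYP2C19	*17	increased_function
CYP2D6	*1	normal
CYP2D6	*2	normal
CYP2D6	*3	inactive
CYP2D6	*4	inactive
CYP2D6	*5	inactive
CYP2D6	*6	inactive
CYP2D6	*7	inactive
CYP2D6	*8	inactive
CYP2D6	*9	reduced
CYP2D6	*10	reduced
CYP2D6	*12	inactive
CYP2D6	*14	reduced
CYP2D6	*17	reduced
CYP2D6	*29	reduced
CYP2D6	*41	reduced
CYP2D6	*46	reduced
CYP3A4	*1	normal
CYP3A4	*1B	inactive
CYP3A5	*1	normal
CYP3A5	*3C	inactive
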