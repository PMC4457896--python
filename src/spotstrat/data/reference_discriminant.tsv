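group	term	value
f1	288	33.813
f1	289	48.942
f1	intercept	-7.155
f2	288	103.508
f2	289	42.871
f2	intercept	-15.248
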