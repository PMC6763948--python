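increase	+1
increased	+1
increases	+1
elevated	+1
enriched	+1
higher	+1
abundant	+1
decrease	-1
decreased	-1
decreases	-1
reduced	-1
depleted	-1
lower	-1
diminished	-1
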