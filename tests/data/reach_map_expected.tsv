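topography_code	reach_category	label
C180	REQUIRES_COLONOSCOPY	Cecum
C182	REQUIRES_COLONOSCOPY	Ascending Colon
C183	REQUIRES_COLONOSCOPY	Hepatic Flexure
C184	REQUIRES_COLONOSCOPY	Transverse Colon
C185	REQUIRES_COLONOSCOPY	Splenic Flexure
C186	VISUALIZABLE	Descending Colon
C187	VISUALIZABLE	Sigmoid
C199	VISUALIZABLE	Rectosigmoid Junction
C209	VISUALIZABLE	Rectum
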