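{"name":"Test series","slices":[
{"nr":2,"filename":"sampleID_s002.png","width":24723,"height":18561,
"anchoring":[312.2,533.8,218.4,-185.7,-35.5,6.6,-4.6,-7.5,-171.4]},
{"nr":8,"filename":"sampleID_s008.png","width":24722,"height":17507,
"anchoring":[334.82142136461607,485.7990978550188,251.62087421842932,-228.6553268,-13.316924663882391,-11.981074687915681,11.021383786310937,-7.15410850678,-202.3881726664459]}
]}
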