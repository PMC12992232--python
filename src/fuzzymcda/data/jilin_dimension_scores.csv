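node,weight,score,description
A1,0.3850984,4,The policy enforcement is strong and the degree of law enforcement standardization is relatively high
A2,0.11727,3,The implementation of the main responsibility is not sufficient
A3,0.2438468,3.5,The detection mechanism is well-developed but has insufficient coverage
A4,0.2537846,3.5,The enthusiasm of the public for supervision needs to be enhanced
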