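{
 "version": "toy-synthetic-3L",
 "constant": 1.0,
 "u_min": -0.3500000000000001,
 "note": "synthetic toy tariff for tests and examples; not a published value set"
}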