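# Reduced-lattice preset for fast exploratory runs and tests.
rows: 200
cols: 200
steps: 80
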