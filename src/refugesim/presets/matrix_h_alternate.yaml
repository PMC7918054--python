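# Alternate high-density payoff matrix quoted in the worked rule example
# (SF intra 0.48 / inter 0.18, HA intra 0.22 / inter 0.47); the canonical
# defaults use the tabulated matrix instead.
beta11: 0.48
beta12: 0.18
beta21: 0.47
beta22: 0.22
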