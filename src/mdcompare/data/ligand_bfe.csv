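replicate,holo,holo-G323E,holo-p
1,-132.5,-75.3,-86.8
2,-113.4,-60.3,-88.1
3,-125.6,-69.2,-103.5
4,-114.9,-70.9,-129.8
5,-135.4,-87.9,-96.8
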