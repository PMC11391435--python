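replicate,holo,holo-G323E,holo-p
1,-1228.0,-1442.5,-1506.7
2,-1142.0,-1721.9,-1500.3
3,-1456.0,-1273.8,-1341.7
4,-1305.0,-1190.5,-1523.5
5,-901.2,-1421.1,-1346.0
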