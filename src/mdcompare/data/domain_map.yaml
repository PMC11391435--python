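# Default six-interface template for a two-chain bHLH-PAS heterodimer
# (chain A = oxygen-sensing subunit, chain B = nuclear translocator).
# Residue ranges use author numbering and are approximate domain bounds;
# override with a system-specific map for production analyses.
domains:
  a_bhlh:  {chain: A, start: 14,  end: 74}
  a_pasa:  {chain: A, start: 85,  end: 200}
  a_pasb:  {chain: A, start: 240, end: 350}
  b_bhlh:  {chain: B, start: 90,  end: 150}
  b_pasa:  {chain: B, start: 160, end: 345}
  b_pasb:  {chain: B, start: 356, end: 470}
interfaces:
  1: [a_bhlh, b_bhlh]   # bHLH:bHLH
  2: [a_pasa, b_pasa]   # PAS-A:PAS-A
  3: [a_pasb, b_pasa]   # chain-A PAS-B : chain-B PAS-A
  4: [a_pasb, b_pasb]   # PAS-B:PAS-B
  5: [a_pasb, a_pasa]   # intrachain PAS-B:PAS-A
  6: [a_pasa, a_bhlh]   # intrachain PAS-A:bHLH
disordered:
  - {chain: A, start: 75,  end: 84}    # bHLH / PAS-A linker
  - {chain: A, start: 201, end: 239}   # PAS-A / PAS-B linker
  - {chain: B, start: 151, end: 159}
  - {chain: B, start: 346, end: 355}
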