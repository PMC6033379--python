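# 39 PDB entries with no missing residues, spanning mainly-alpha,
# mainly-beta, alpha-beta and low-regular-structure proteins, used by the
# residue-masking robustness protocol.  Fetching these files requires
# network access; all packaged tests run on synthetic traces instead.
1XMK
1MZ9
1QSA
3IIS
1GXM
4K12
4HI8
4DEQ
1UUN
4GV5
2AYD
2O9S
2EVB
3WJT
2E5Y
4A02
3NBC
2DPF
1VMO
3DCL
3C7X
1TL2
1PJX
2XDW
1W6S
1M8N
4E2V
1IGD
1EWF
4BEU
1VBM
2HBA
1A9X
1DL5
1HQ0
1UD9
2CI1
1J0P
1V54
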