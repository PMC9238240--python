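# Reconstructed 3-(phenoxymethyl)biphenyl core for the PD-L1 inhibitor series,
# with seven numbered attachment points: R1 on the distal phenyl ring, R2/R3
# ortho positions on the central biphenyl ring, R4-R7 around the terminal
# phenoxy ring.  The published site numbering is only available graphically,
# so this placement is a best-effort reconstruction and should be validated
# against an authoritative R-group decomposition table when one is available.
core: "[*:1]c1ccc(cc1)-c1c([*:2])cc(COc2cc([*:4])c([*:5])c([*:6])c2[*:7])cc1[*:3]"
site_labels: [R1, R2, R3, R4, R5, R6, R7]
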