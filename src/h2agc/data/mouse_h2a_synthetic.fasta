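>H2A3_mouse_synthetic species=mouse reconstructed Ser40-type canonical H2A (initiator Met removed); G37-K74 span cross-validated against m/z 1327.02 (z=3)
SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRLLRKGNYSERVGAGAPVYLAAVLEYLT
AEILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPK
KTESHHKAKGK
>H2A1A_mouse_synthetic species=mouse reconstructed Ala40-type canonical H2A (Ser40Ala counterpart of the Ser40-type backbone)
SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRLLRKGNYAERVGAGAPVYLAAVLEYLT
AEILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPK
KTESHHKAKGK
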