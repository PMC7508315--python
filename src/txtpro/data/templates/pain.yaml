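template_id: pain
kind: pair_list
header: P
intensity_range: [1, 10]
location_vocabulary: [HEAD, CHEST, BELLY, BACK, UL, UR, LL, LR]
no_event_response: PN
valid_example: P2CHEST&3BELLY
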