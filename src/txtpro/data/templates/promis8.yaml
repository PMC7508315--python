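template_id: promis8
kind: digit_vector
item_count: 8
item_range: [0, 4]
valid_example: "01324101"
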