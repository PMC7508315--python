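template_id: attendance
kind: code_choice
code_options: [WD, AM, AF, AW]
valid_example: WD
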