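# Default longitudinal relaxation times at 1.5 T, from the literature.
t1_ms:
  fat: 296            # breast adipose tissue
  skin: 887
  muscle: 1130        # chest-wall muscle
  fibroglandular: 1266
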