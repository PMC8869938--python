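["P286R", "V411L", "S297F", "A456P", "F367S", "L424I", "M295R", "P436R", "M444K", "D368Y", "S459F"]
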