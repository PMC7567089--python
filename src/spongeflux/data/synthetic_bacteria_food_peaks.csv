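sample_id,fatty_acid,area,delta13c_fame
bacteria_food,C16:0,214200.0,-26.823529
bacteria_food,C18:1,569050.0,-26.736842
bacteria_food,C18:0,168150.0,-26.736842
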