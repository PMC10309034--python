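image_size: 64
batch_size: 8
depth: tiny
epochs: 20
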