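# Window/level presets (HU) for 3-channel CT input stacking.
soft: {width: 400, level: 50}
bone: {width: 1800, level: 400}
custom: {width: 500, level: 50}
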