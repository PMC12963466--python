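# Display-window presets (center/width in HU).
[windows.soft_tissue]
center = 50.0
width = 400.0

[windows.bone]
center = 300.0
width = 1120.0
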