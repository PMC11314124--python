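use_sac: true
use_sod: false
use_cbam: false
num_classes: 2
depth_multiple: 0.33
width_multiple: 0.25
max_channels: 1024
input_size: 640
sac_rate: 3
sac_stages:
- 4
cbam_ratio: 8
cbam_sites: after_every_c2f_and_sppf
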