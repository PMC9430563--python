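# 5-day, 3-channel acquisition at 30-minute intervals.
# bytes_per_timepoint is measured from a pilot acquisition, not derived
# from pixel dimensions (real files carry container/metadata overhead).
drift_rate: 2.5        # um/h of axial surface descent
duration: 120.0        # h
interval: 30.0         # min between timepoints
z_step: 2.0            # um
n_channels: 3          # two fluorescence + transmitted light
sec_per_slice: 3.0     # s to acquire one multichannel slice
bytes_per_timepoint: 660000000.0
safety_margin: 0.0     # extra um beyond predicted drift
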