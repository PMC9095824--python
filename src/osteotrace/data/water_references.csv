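region,d18O_water_min,d18O_water_max
Punjab,-9.0,-6.5
GangeticPlain,-6.5,-3.5
CoastalOrissa,-3.5,-1.0
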