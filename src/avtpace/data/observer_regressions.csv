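observer,method,gradient_ms_per_bpm,intercept_ms,r_squared
calculated,M10,-0.28,143,0.87
calculated,M20,-0.56,209,0.94
I,M10,-2.06,506,0.97
I,M20,-2.06,516,0.97
II,M10,-0.49,196,0.97
II,M20,-0.58,206,0.93
III,M10,-0.48,174,0.97
III,M20,-0.48,168,0.97
IV,M10,-0.50,195,1.0
IV,M20,-0.50,200,1.0
V,M10,-0.29,140,0.94
V,M20,-0.33,140,0.97
VI,M10,-0.48,191,0.99
VI,M20,-0.46,179,0.99
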