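mtr_bpm,vai_max_ms
90,400
100,400
110,400
120,400
130,390
140,350
150,320
160,300
170,280
180,260
190,240
200,220
210,210
220,200
230,190
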