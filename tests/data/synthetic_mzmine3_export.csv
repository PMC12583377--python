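row ID,row m/z,row retention time,C1_S1.mzML Peak area,T1_S1.mzML Peak area,B1.mzML Peak area
1,301.1406,9.416,152340.5,648210.8,0.0
2,302.1440,9.416,45702.1,194463.2,0.0
3,415.2110,12.052,88210.0,91050.3,30210.7
4,219.0874,6.233,12500.9,13100.4,0.0
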