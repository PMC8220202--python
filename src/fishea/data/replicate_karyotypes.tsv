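# G-band karyotypes of the six BEC20W replicate wells after 14 further weeks
# with (exposed) and without (unexposed) acidified-bile-salt exposure.
replicate_id	condition	karyotype
well1	unexposed	47,XY,add(4)(p16.1),add(7)(p22),i(8)(q10),+20
well2	unexposed	47,XY,add(4)(p16.1),add(7)(p22),i(8)(q10),+20
well3	unexposed	47,XY,add(4)(p16.1),add(7)(p22),i(8)(q10),+20
well4	unexposed	47,XY,add(4)(p16.1),add(7)(p22),i(8)(q10),+20
well5	unexposed	47,XY,add(4)(p16.1),add(7)(p22),i(8)(q10),+20
well6	unexposed	47,XY,add(4)(p16.1),add(7)(p22),i(8)(q10),+20
well1	exposed	48,XY,i(8)(q10),t(2;10;16)(p22;q22;q22),+20,+20
well2	exposed	47,XY,add(7)(p22),i(8)(q10),+20
well3	exposed	48,XY,i(8)(q10),t(2;10;16)(p22;q22;q21),+20,+20
well4	exposed	47,XY,add(7)(p22),i(8)(q10),+20
well5	exposed	48,XY,i(8)(q10),t(2;10;16)(p22;q22;q21),+20,+20
well6	exposed	48,XY,i(8)(q10),t(2;10;16)(p22;q22;q21),+20,+20
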