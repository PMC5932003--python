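# Draftinge Mosse (southern Sweden) radiocarbon date table, as printed.
# reported_cal_min/max are the published 95% calibrated ranges (cal yr BP),
# carried for reference only; they are not inputs to any computation.
depth_cm,lab_id,material,c14_age,c14_error,is_bulk,reported_cal_min,reported_cal_max
28,Ua-010650,Bulk peat,554,23,1,524,561
49,Ua-010654,Sphagnum leaves & stems,835,24,0,594,786
77,Ua-010651,Bulk peat,1259,24,1,1173,1279
97,Beta-418758,Sphagnum stems; seeds,1970,30,0,1866,1993
117,Beta-418759,Sphagnum stems; seeds; insect remains,2390,30,0,2346,2491
136,Beta-385361,Sphagnum leaves; insect remains; charcoal,4070,30,0,4499,4644
179,Ua-010655,Sphagnum leaves & stems,4401,26,0,4866,5047
219,Ua-010656,Sphagnum leaves & stems,4485,25,0,5211,5278
247,Beta-387826,Sphagnum leaves and stems,4690,30,0,5326,5405
292,Beta-385362,Intact pine cone,4740,30,0,5510,5580
308,Ua-010652,Bulk peat,5763,26,1,6492,6639
323,Beta-387827,Charcoal; Carex,5180,30,0,5906,5990
338,Ua-010653,Bulk peat,6932,27,1,7689,7828
356,Beta-385363,Charcoal; Carex,6470,30,0,7321,7432
389,Beta-385364,Seeds; insect remains; Carex,7510,30,0,8299,8391
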