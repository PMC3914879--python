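column,ILM,NFL/GCL,IPL/INL,INL/OPL,OPL/ONL,ELM,IS/OS,OS/RPE,RPE/choroid
0,506.791852,536.065568,621.341176,662.069825,687.52523,765.164216,800.801784,841.530433,878.440771
128,500.762396,530.036113,615.311721,656.040369,681.495775,759.134761,794.772329,835.500977,872.411315
256,491.301459,520.575169,605.850757,646.579396,672.034796,749.673782,785.31135,826.039999,862.950336
384,488.469427,517.742524,603.01633,643.744118,669.198985,746.837972,782.475539,823.204188,860.114526
512,484.274542,513.523447,598.72678,639.420909,664.85474,742.493727,778.131294,818.859943,855.770281
640,479.817749,508.653428,592.653015,632.772221,657.846725,735.485711,771.123279,811.851927,848.762265
768,496.368687,522.237286,597.593639,633.584733,656.079167,733.718154,769.355721,810.08437,846.994708
896,546.579041,564.197957,615.522624,640.035898,655.356694,732.99568,768.633248,809.361897,846.272234
1024,584.508361,596.217847,630.32809,646.61955,656.801712,734.440698,770.078266,810.806915,847.717252
1152,549.327002,566.945917,618.270584,642.783858,658.104654,735.74364,771.381208,812.109857,849.020195
1280,496.089166,521.957765,597.314118,633.305212,655.799646,733.438633,769.0762,809.804849,846.715187
1408,481.504728,510.340407,594.339995,634.4592,659.533704,737.172691,772.810258,813.538907,850.449245
1536,483.688669,512.937574,598.140907,638.835036,664.268867,741.907854,777.545421,818.27407,855.184408
1664,484.454802,513.7279,599.001705,639.729493,665.18436,742.823347,778.460915,819.189563,856.099901
1792,492.574119,521.847828,607.123417,647.852056,673.307455,750.946442,786.584009,827.312658,864.222996
1920,501.887504,531.16122,616.436828,657.165477,682.620882,760.259869,795.897436,836.626085,873.536423
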