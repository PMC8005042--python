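id,docking_score,GIAN,GIAT,SGCA,RF,SVR,multi_target
ZINC8577218,64.296,7.301,7.765,7.235,6.613,5.790,0
ZINC15919406,63.009,6.724,5.593,6.858,6.002,6.384,0
ZINC2036915,62.93,7.608,7.820,6.586,6.611,5.619,0
ZINC3952167,62.463,6.645,6.336,5.167,5.661,6.242,0
ZINC43100953,61.858,5.847,7.543,7.401,5.710,7.242,0
ZINC3831490,61.751,6.627,7.417,7.191,6.074,6.129,0
ZINC4261765,60.522,8.058,10.816,12.787,5.873,5.991,1
ZINC1530605,60.384,5.740,7.980,6.135,7.431,6.689,0
ZINC1587572,59.994,7.608,7.820,6.586,6.664,5.595,0
ZINC95618747,59.621,7.532,10.966,12.392,5.846,6.141,1
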