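county,2000,2005,2010,2015
Lushi,10.307,10.306,10.281,10.307
Lushan,5.484,5.523,5.636,5.623
Luanchuan,8.192,8.177,8.090,8.077
Nanzhao,7.924,8.089,8.135,8.116
Neixiang,5.290,5.295,5.301,5.289
Ruyang,3.162,3.160,3.150,3.143
Songxian,8.575,8.577,8.496,8.485
Xixia,10.900,10.895,10.872,10.852
Xichuan,5.699,5.887,5.865,5.862
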