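letter,p1,p2,p3,p4,p5,p6,p7,p8,p9
a,0.0,0.1267,0.0,0.0344,0.4589,0.0233,0.0,0.1189,0.0044
b,0.23,0.23,0.08,0.26,0.12,0.22,0.01,0.18,0.01
c,0.0,0.1189,0.0,0.0122,0.2544,0.0,0.0,0.1111,0.0
d,0.01,0.17,0.0,0.23,0.13,0.22,0.23,0.23,0.08
e,0.0,0.1144,0.0,0.0578,0.4022,0.05,0.0,0.1167,0.0056
f,0.0,0.14,0.0,0.0,0.2944,0.0,0.0,0.08,0.0
g,0.0144,0.2356,0.0133,0.0744,0.4033,0.0322,0.0,0.19,0.0
h,0.0144,0.0722,0.0,0.0333,0.4311,0.0344,0.0133,0.1333,0.0267
i,0.0,0.0533,0.0,0.0,0.18,0.0,0.0,0.08,0.0
j,0.0,0.08,0.0,0.0,0.2,0.0,0.0,0.16,0.0
k,0.0,0.0867,0.0,0.0,0.4333,0.0111,0.0,0.18,0.0167
l,0.0,0.0867,0.0,0.0,0.2,0.0,0.0,0.08,0.0
m,0.0411,0.1067,0.0467,0.2278,0.2667,0.2144,0.0333,0.0389,0.0333
n,0.0044,0.11,0.0,0.0333,0.3822,0.05,0.0056,0.0556,0.0111
o,0.0,0.1133,0.0,0.0589,0.3689,0.0611,0.0,0.1022,0.0
p,0.0133,0.2333,0.0122,0.0333,0.4044,0.0722,0.0133,0.0667,0.0
q,0.0133,0.2344,0.0133,0.0756,0.4044,0.0333,0.0,0.0667,0.0133
r,0.0,0.0944,0.0,0.0,0.2356,0.0,0.0,0.0333,0.0
s,0.0,0.1189,0.0,0.0,0.3522,0.0,0.0,0.1222,0.0
t,0.0,0.0667,0.0,0.0,0.3056,0.0,0.0,0.1311,0.0
u,0.0111,0.0556,0.0056,0.0556,0.38,0.0333,0.0,0.1122,0.0044
v,0.0122,0.0344,0.0156,0.0056,0.4344,0.0089,0.0,0.0456,0.0
w,0.0289,0.0411,0.0289,0.1689,0.4467,0.1856,0.0056,0.0622,0.0089
x,0.0022,0.0589,0.0056,0.0011,0.4644,0.0011,0.0111,0.0444,0.0122
y,0.02,0.1356,0.0267,0.0,0.3922,0.0,0.0,0.1222,0.0
z,0.0,0.1333,0.0044,0.0022,0.2911,0.0022,0.0044,0.1333,0.0044
è,0.0,0.09,0.0,0.0489,0.4411,0.0422,0.0089,0.2033,0.0133
é,0.0,0.09,0.0,0.0489,0.4411,0.0422,0.0089,0.2033,0.0133
î,0.0,0.1444,0.0,0.0,0.1667,0.0,0.0,0.0933,0.0
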