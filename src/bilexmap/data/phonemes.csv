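symbol,kind,cv,place,manner
p,C,0.5,0.1,0.1
b,C,0.5,0.14,0.1
t,C,0.5,0.38,0.1
d,C,0.5,0.42,0.1
k,C,0.5,0.75,0.1
g,C,0.5,0.79,0.1
f,C,0.5,0.22,0.32
v,C,0.5,0.26,0.32
s,C,0.5,0.38,0.32
z,C,0.5,0.42,0.32
ʃ,C,0.5,0.5,0.32
ʒ,C,0.5,0.54,0.32
x,C,0.5,0.75,0.32
ɣ,C,0.5,0.79,0.32
ʁ,C,0.5,0.92,0.32
h,C,0.5,1.0,0.32
m,C,0.5,0.14,0.54
n,C,0.5,0.42,0.54
ɲ,C,0.5,0.66,0.54
ŋ,C,0.5,0.79,0.54
l,C,0.5,0.42,0.7
r,C,0.5,0.42,0.85
j,C,0.5,0.66,1.0
w,C,0.5,0.79,1.0
ʋ,C,0.5,0.26,1.0
ɥ,C,0.5,0.66,1.0
i,V,1.0,0.1,0.1
y,V,1.0,0.2,0.1
u,V,1.0,0.9,0.1
ɪ,V,1.0,0.1,0.25
ʏ,V,1.0,0.2,0.25
e,V,1.0,0.1,0.4
ø,V,1.0,0.2,0.4
o,V,1.0,0.9,0.4
ə,V,1.0,0.5,0.55
ɛ,V,1.0,0.1,0.7
œ,V,1.0,0.2,0.7
ɔ,V,1.0,0.9,0.7
ʌ,V,1.0,0.9,0.7
a,V,1.0,0.1,0.95
ɑ,V,1.0,0.9,0.95
ɛ̃,V,1.0,0.1,0.73
œ̃,V,1.0,0.2,0.73
ɔ̃,V,1.0,0.9,0.73
ɑ̃,V,1.0,0.9,0.98
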