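e.g.
i.e.
i.v.
i.m.
p.o.
b.i.d.
t.i.d.
q.d.
et al.
fig.
figs.
dr.
vs.
ca.
resp.
approx.
no.
spp.
subsp.
cf.
wt.
vol.
pp.
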