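# SYNTHETIC fixture: hand-designed stand-in values for the canonical topology,
# not literature measurements. RibA (GTPCHII+DHBPS) carries the smallest capacity
# by construction.
# kinetic parameters: Vmax in nmol/mg/min, Km in nM
reaction_id,vmax,km_a,km_b
GTPCHII,45.0,2000.0,
DHBPS,90.0,3000.0,
PYRD,600.0,1000.0,
PYRR,700.0,1000.0,
PHOSPHATASE,800.0,1000.0,
ARP_TRANSPORT,900.0,1000.0,
LS,1500.0,1000.0,1500.0
RS,400.0,4000.0,
RK,500.0,50000.0,100000.0
FAD_TRANSPORT,60.0,50000.0,
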