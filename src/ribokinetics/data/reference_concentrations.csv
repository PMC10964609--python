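# SYNTHETIC fixture: analytic baseline operating point of the reference model.
# initial concentrations in nM
metabolite_id,conc_nM
GTP,4000.0
RUB5P,6000.0
DA6RP5P,52.63157894736842
A6RP5P,44.776119402985074
ARPP,38.96103896103896
ARPc,34.48275862068966
ARPp,250.0
DHB4P,375.0
DMRYL,324.3243243243243
RIBO,3304.904051172708
FMN,5000.0
FAD,25000.0
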