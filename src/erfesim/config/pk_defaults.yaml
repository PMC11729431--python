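# Default drug-kinetics constants for the rHuEPO and carboplatin PK models.
#
# SYNTHETIC PLACEHOLDER VALUES. The PD parameter tables this package ships do
# not come with companion PK estimates, so these constants were chosen to give
# pharmacologically plausible rat exposure profiles (see docs/methods.md):
#   - rHuEPO: two-compartment, parallel linear + Michaelis-Menten elimination;
#     1350 IU/kg i.v. gives C0 ~ 2.2e4 mIU/mL decaying through both EC50
#     regimes within 24 h.
#   - carboplatin: three-compartment linear; 60 mg/kg i.v. gives a brief,
#     intense exposure driving a moderate precursor-kill integral.
# Swap this file via --pk-config / load_pk_config(path) without code changes.
#
# Units: rate constants 1/h; vmax IU/kg/h; km mIU/mL; vc L/kg.
rhuepo:
  vmax: 40.0
  km: 1000.0
  kel: 0.45
  kpt: 0.08
  ktp: 0.05
  vc: 0.06
carboplatin:
  kel: 0.8
  k12: 0.15
  k21: 0.08
  k13: 0.03
  k31: 0.01
  vc: 0.25
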