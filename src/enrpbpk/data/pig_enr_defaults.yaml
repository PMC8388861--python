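# Default parameterization: enrofloxacin granules given orally to grower pigs
# (55 kg), with ciprofloxacin formed by hepatic metabolism.
#
# Physiology: standard grower-pig organ weight and blood-flow fractions from
# the veterinary PBPK literature; cardiac output scales allometrically
# (QCC * BW^0.75).  Chemical constants are literature-informed for oral
# fluoroquinolones in swine: moderate oral absorption with partial fecal
# loss, ~4% of hepatically cleared ENR emerging as CIP, high tissue:plasma
# partitioning typical of fluoroquinolones (lysosomal trapping), and slow
# renal elimination of the metabolite.  Concentration unit: mg/L == ug/mL.
physiology:
  BW: 55.0                 # kg body weight
  QCC: 8.7                 # L/h per kg^0.75 cardiac output coefficient
  cardiac_exponent: 0.75
  clearance_exponent: 0.75 # clearances scale allometrically (BW^0.75)
  flow_fractions:          # fraction of cardiac output
    liver: 0.24            # total hepatic (arterial + portal)
    kidney: 0.11
    muscle: 0.30
    fat: 0.13
    rest: 0.22
  volume_fractions:        # fraction of body weight; remainder unperfused
    blood: 0.044
    lung: 0.008
    liver: 0.023
    kidney: 0.0045
    muscle: 0.40
    fat: 0.23
    rest: 0.2405
chemical:
  Ka: 0.35                 # 1/h intestinal absorption
  Kint: 0.15               # 1/h intestinal transit (fecal loss)
  Kst: 1.5                 # 1/h gastric emptying
  Frac: 0.04               # mass fraction of hepatic clearance -> CIP
  KmC: 0.22                # L/h/kg^0.75 hepatic metabolic clearance of ENR
  KurineC: 0.11            # L/h/kg^0.75 urinary clearance of ENR
  Kurine1C: 0.16           # L/h/kg^0.75 urinary clearance of CIP
  pc_enr:                  # tissue:plasma partition coefficients, ENR
    liver: 7.0
    kidney: 7.0
    muscle: 2.5
    fat: 0.8
    lung: 4.0
    rest: 6.0
  pc_cip:                  # tissue:plasma partition coefficients, CIP
    liver: 6.0
    kidney: 8.0
    muscle: 2.2
    fat: 0.7
    lung: 3.5
    rest: 5.0
dosing:
  dose_mg_per_kg: 5.0      # label dose
  interval_h: 12.0         # twice daily
  n_doses: 10              # 5 days
  t_end_h: 228.0           # 5 d of depletion after the last dose at 108 h
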