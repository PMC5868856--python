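# Species archetypes spanning the four single-species characters on the
# abstract proton scale p in [0, 2b] (high p displays as low pH).
#   acid_lover_acidifier   : prefers high p and raises p  -> Allee effect
#   alkali_lover_alkalizer : prefers low p and lowers p   -> Allee effect
#   acid_lover_alkalizer   : prefers high p but lowers p  -> ecological suicide
#   mid_lover_acidifier    : prefers mid-low p but raises p -> ecological suicide
# delta = 0.5, |c| = 0.1, b = 5 throughout; K, sigma and the p_pref values are
# declared model defaults (sigma = 4 except for the acid-loving alkalizer,
# whose narrower niche and doubled relative drive strength d let rare-killer
# cocultures sustain oscillatory rescue instead of converging).
environment:
  b: 5.0
  p0: 5.0
species:
  acid_lover_acidifier:     # "Lp-like"
    p_pref: 8.0
    sigma: 4.0
    delta: 0.5
    c: 0.1
    d: 1.0
    K: 10.0
  alkali_lover_alkalizer:   # "Ca-like"
    p_pref: 2.0
    sigma: 4.0
    delta: 0.5
    c: -0.1
    d: 1.0
    K: 10.0
  acid_lover_alkalizer:     # "Pv-like"
    p_pref: 8.5
    sigma: 2.5
    delta: 0.5
    c: -0.1
    d: 2.0
    K: 10.0
  mid_lover_acidifier:      # "Sm-like"
    p_pref: 3.5
    sigma: 4.0
    delta: 0.5
    c: 0.1
    d: 1.0
    K: 10.0
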