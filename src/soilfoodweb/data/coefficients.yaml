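# Editable coefficient tables for the energetics module.
#
# metabolic: ln I = ln_b0 + a*ln(M mg) - E/(k*T), I in J h^-1.
#   Default constants are the cross-group invertebrate regression of
#   Ehnes, Rall & Brose (2011, Ecol. Lett. 14:993-1000); replace with
#   group-specific fits where available.
# allometry: log10(mass mg) = a_len + b_len*log10(length mm).
#   Illustrative defaults in the range of published microarthropod and
#   macrofauna length-mass regressions; provenance per row, user-editable.
# efficiencies: assimilation efficiency per basal resource id.

metabolic:
  invertebrate:
    ln_b0: 23.055
    a: 0.695
    E: 0.686
    provenance: "Ehnes et al. 2011, all invertebrates"
  insect:
    ln_b0: 21.972
    a: 0.759
    E: 0.657
    provenance: "Ehnes et al. 2011, Insecta"
  oligochaete:
    ln_b0: 22.347
    a: 0.713
    E: 0.671
    provenance: "placeholder near the all-group fit; edit for Oligochaeta"

allometry:
  springtail:
    a_len: -0.52
    b_len: 2.6
    provenance: "illustrative microarthropod regression"
  oribatid_mite:
    a_len: -0.67
    b_len: 2.9
    provenance: "illustrative microarthropod regression"
  earthworm:
    a_len: -0.7
    b_len: 2.5
    provenance: "illustrative macrofauna regression"

efficiencies:
  P: 0.21
  L: 0.18
  S: 0.13
  B: 0.96
  F: 0.36
  A: 0.36
  W: 0.18
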