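# Worked-example run manifest: the three intensively sampled sites with
# their benthic (F_sed) and in-situ sea-air (F_atm) fluxes, mmol m^-2 d^-1.
sites:
  - site_id: Sodra_Vaxholmsfjarden
    F_sed: 2.4
    F_atm: 0.2
    redox: oxic
  - site_id: Stora_Vartan
    F_sed: 5.6
    F_atm: 0.1
    redox: euxinic
  - site_id: Skurusundet
    F_sed: 2.2
    F_atm: 1.7
    redox: euxinic
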