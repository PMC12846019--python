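# Packaged default parameter registries (mg/kg dry weight unless noted).
limits:
  default: {As: 2.0, Hg: 0.2, Pb: 5.0, Cd: 1.0, Cu: 20.0}
  overrides:
    Sepiae Endoconcha: {As: 10.0, Hg: 0.2, Pb: 5.0, Cd: 5.0, Cu: 20.0}
    Hirudo: {As: 5.0, Hg: 1.0, Pb: 10.0, Cd: 1.0, Cu: 20.0}
lod: {As: 1.0e-4, Hg: 3.0e-6, Pb: 1.2e-4, Cd: 3.0e-6, Cu: 0.02}
exposure: {EF: 90.0, ED: 20.0, BW: 60.0, AT: 25550.0}
toxicity:
  transfer: {As: 0.35, Hg: 0.24, Pb: 0.14, Cd: 0.14, Cu: 0.14}
  rfd: {As: 3.0e-4, Hg: 3.0e-4, Pb: 3.5e-3, Cd: 1.0e-3, Cu: 0.04}
  csf: {As: 1.5, Pb: 8.5e-3, Cd: 6.1}
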