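# Example scenario for `msmiss experiment`:
# all five strategies under MCAR missingness calibrated to 40%.
name: mcar_main
dgm: {}            # defaults; any DGMConfig field can be overridden here
missingness:
  mechanism: MCAR
  target: 0.40
methods: [cc, locf, mpa, mi, ipmw]
n: 10000
reps: 200
imputations: 10
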