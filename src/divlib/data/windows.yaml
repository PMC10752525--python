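# Staged physicochemical windows (all closed intervals).
wide:
  mwt: {max: 450}
  slogp: {max: 5}
  hbd: {max: 4}
  hba: {max: 8}
  rotb: {max: 8}
crude:
  mwt: {min: 320, max: 420}
  slogp: {min: 0, max: 4.5}
  hbd: {min: 0, max: 3}
  hba: {min: 0, max: 8}
  rotb: {min: 1, max: 8}
agreed:
  mwt: {min: 320, max: 380}
  slogp: {min: 1, max: 3}
  hba: {min: 0, max: 8}
  hbd: {min: 0, max: 3}
  sfi: {min: 2, max: 6}
  rotb: {min: 1, max: 7}
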