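{
  "_comment": "Package-derived default EC-domain boundaries (author numbering, inclusive). Only the construct termini are anchored by published boundaries (Fat4 EC1-3 ends at 353, EC1-4 at 475; Dchs1 EC1-3 ends at 362, EC1-4 at 472); interior splits interpolate ~105-residue cadherin repeats and should be overridden when calcium-linker positions are known.",
  "fat4": [
    {"domain": "EC1", "start": 43, "end": 147},
    {"domain": "EC2", "start": 148, "end": 250},
    {"domain": "EC3", "start": 251, "end": 353},
    {"domain": "EC4", "start": 354, "end": 475}
  ],
  "dchs1": [
    {"domain": "EC1", "start": 43, "end": 150},
    {"domain": "EC2", "start": 151, "end": 255},
    {"domain": "EC3", "start": 256, "end": 362},
    {"domain": "EC4", "start": 363, "end": 472}
  ]
}
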