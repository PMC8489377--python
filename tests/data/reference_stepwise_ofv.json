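{
  "comment": "Recorded OFVs of the published stepwise covariate search for the normal-renal-function model (base one-compartment model, maturation screening, forward addition, backward exclusion). 'covariates' lists the clearance covariates of each evaluated model; 'WT' denotes the structural weight allometry on CL and V.",
  "base_ofv": 715.776,
  "maturation": {
    "I": 632.709,
    "II": 637.799,
    "III": 663.949,
    "IV": 646.078,
    "V": 671.471
  },
  "models": [
    {"covariates": ["WT"], "ofv": 632.709},
    {"covariates": ["WT", "COMED"], "ofv": 631.345},
    {"covariates": ["WT", "SEX"], "ofv": 631.858},
    {"covariates": ["WT", "AGE"], "ofv": 632.462},
    {"covariates": ["WT", "HT"], "ofv": 628.091},
    {"covariates": ["WT", "ALT"], "ofv": 632.706},
    {"covariates": ["WT", "AST"], "ofv": 632.708},
    {"covariates": ["WT", "BUN"], "ofv": 626.547},
    {"covariates": ["WT", "SCR"], "ofv": 611.910},
    {"covariates": ["WT", "CYSC"], "ofv": 627.555},
    {"covariates": ["WT", "ALB"], "ofv": 632.315},
    {"covariates": ["WT", "TP"], "ofv": 632.552},
    {"covariates": ["WT", "EGFR"], "ofv": 620.829},
    {"covariates": ["WT", "SCR", "BUN"], "ofv": 610.667},
    {"covariates": ["WT", "SCR", "EGFR"], "ofv": 606.684},
    {"covariates": ["WT", "SCR", "HT"], "ofv": 606.057},
    {"covariates": ["WT", "SCR", "CYSC"], "ofv": 609.149},
    {"covariates": ["WT", "SCR", "HT", "EGFR"], "ofv": 603.087},
    {"covariates": ["HT", "SCR"], "ofv": 688.498}
  ]
}
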