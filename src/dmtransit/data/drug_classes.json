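{
 "comment": "Canonical drug -> therapeutic class. Combination products list their components under 'combinations'.",
 "classes": {
  "metformin": "hypoglycemic_first_line",
  "empagliflozin": "hypoglycemic_second_line",
  "dapagliflozin": "hypoglycemic_second_line",
  "sitagliptin": "hypoglycemic_second_line",
  "glibenclamide": "hypoglycemic_second_line",
  "insulin": "insulin",
  "insulin glargine": "insulin",
  "insulin aspart": "insulin",
  "enalapril": "antihypertensive",
  "losartan": "antihypertensive",
  "amlodipine": "antihypertensive",
  "metoprolol": "antihypertensive",
  "metoprolol succinate": "antihypertensive",
  "hydrochlorothiazide": "antihypertensive",
  "atorvastatin": "lipid_lowering",
  "rosuvastatin": "lipid_lowering",
  "omeprazole": "antacid",
  "acetaminophen": "analgesic",
  "testosterone": "other",
  "carbamazepine": "other",
  "clopidogrel": "other",
  "mycophenolate": "other"
 },
 "combinations": {
  "empagliflozin+metformin": ["empagliflozin", "metformin"],
  "losartan+hydrochlorothiazide": ["losartan", "hydrochlorothiazide"]
 }
}
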