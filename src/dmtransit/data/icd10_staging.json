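{
 "comment": "ICD-10 code prefixes mapping to the three staging complications. Synthetic stand-in for the study's code list; matching is by prefix and the list is user-replaceable.",
 "retinopathy": ["E11.3", "E10.3", "H36"],
 "cerebrovascular disease": ["I60", "I61", "I62", "I63", "I64", "I65", "I66", "I67", "I69", "G45"],
 "chronic kidney disease": ["N18", "E11.2", "E10.2"]
}
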