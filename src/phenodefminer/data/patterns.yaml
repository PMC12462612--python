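# Regular-expression library for measurable values and code mentions.
# These expressions are documented stand-ins: they capture the canonical
# surface forms of each quantity (blood pressure readings, laboratory
# values with clinical units, age/height/weight/BMI statements, ICD and
# CPT code mentions) without attempting full clinical-text coverage.
# All patterns are compiled case-insensitively.
blood_pressure: '(?<![\w./])\d{2,3}\s*/\s*\d{2,3}(?:\s*mm\s*hg)?(?![\w/])'
lab_value: '(?<![\w.])\d+(?:\.\d+)?\s*(?:%|mg/dl|mg/l|mmol/l|mmol/mol|g/dl|g/l|iu/l|u/l|ng/ml|pg/ml|meq/l|cells/mm3)(?![\w/])'
age: '(?<![\w.])(?:aged?\s+\d{1,3}|\d{1,3}\s*(?:-|\s)?\s*(?:years?|yrs?)(?:\s*(?:of\s+age|old))?)(?![\w])'
height: '(?<![\w.])\d{2,3}(?:\.\d+)?\s*(?:cm|centimetres?|centimeters?|metres?|meters?)(?:\s+(?:tall|in\s+height))?(?![\w/])'
weight: '(?<![\w.])\d{1,3}(?:\.\d+)?\s*(?:kg|kilograms?|lbs?|pounds?)(?!\s*/)(?![\w])'
bmi: '(?:(?<![\w.])\d{1,2}(?:\.\d+)?\s*kg\s*/\s*m2?(?![\w])|(?:bmi|body\s+mass\s+index)\s*(?:of|was|is|>=?|<=?|≥|≤|=)?\s*\d{1,2}(?:\.\d+)?)'
icd_code: '\bicd[- ]?(?:9|10)?(?:[- ]?cm)?(?:\s+(?:diagnosis\s+)?codes?)?\s+[a-z]?\d{2,3}(?:\.\d{1,2})?(?![\w.])'
cpt_code: '\bcpt(?:\s+codes?)?\s+\d{4,5}(?![\w])'
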