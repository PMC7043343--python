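detailed_pattern	broad_category
abscess	Abscess
skin	Skin
sputum	Respiratory
throat	Respiratory
oral	Respiratory
tongue	Respiratory
buccal	Respiratory
nares	Respiratory
supragingival	Respiratory
urine	Urinary tract
urinary	Urinary tract
blood	Blood
bone	Bone
joint	Joint
peritoneal	Peritoneal fluid
wound	Wound
feces	Gastrointestinal
stool	Gastrointestinal
gastrointestinal	Gastrointestinal
vaginal	Urogenital
posterior fornix	Urogenital
eye	Eye
hardware	Medical hardware
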