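# english_label	zh_surfaces (|-separated)
hyperglycemia	高血糖
hypertension	高血压
hypoglycemic drugs	降血糖类药|降糖药
blood glucose	葡萄糖|血糖
glucose oral liquid	葡萄糖口服液
diabetes	糖尿病
heart failure	心衰|心力衰竭
coronary heart disease	冠心病
captopril	卡托普利
aspirin	阿司匹林
metformin	二甲双胍
blood pressure	血压
stent implant	支架植入术
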