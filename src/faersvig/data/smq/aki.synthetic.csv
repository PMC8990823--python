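smq_name,scope,pt
Acute kidney injury,narrow,Acute kidney injury
Acute kidney injury,narrow,Anuria
Acute kidney injury,narrow,Azotaemia
Acute kidney injury,narrow,Continuous haemodiafiltration
Acute kidney injury,narrow,Dialysis
Acute kidney injury,narrow,Haemodialysis
Acute kidney injury,narrow,Neonatal anuria
Acute kidney injury,narrow,Nephropathy toxic
Acute kidney injury,narrow,Oliguria
Acute kidney injury,narrow,Peritoneal dialysis
Acute kidney injury,narrow,Prerenal failure
Acute kidney injury,narrow,Renal failure
Acute kidney injury,narrow,Renal failure acute
Acute kidney injury,narrow,Renal failure neonatal
Acute kidney injury,narrow,Renal impairment
Acute kidney injury,narrow,Renal impairment neonatal
Acute kidney injury,narrow,Renal tubular necrosis
Acute kidney injury,narrow,Subacute kidney injury
Acute kidney injury,narrow,Dialysis device insertion
Acute kidney injury,broad,Blood creatinine abnormal
Acute kidney injury,broad,Blood creatinine increased
Acute kidney injury,broad,Blood urea abnormal
Acute kidney injury,broad,Blood urea increased
Acute kidney injury,broad,Blood urea nitrogen/creatinine ratio increased
Acute kidney injury,broad,Creatinine renal clearance abnormal
Acute kidney injury,broad,Creatinine renal clearance decreased
Acute kidney injury,broad,Glomerular filtration rate abnormal
Acute kidney injury,broad,Glomerular filtration rate decreased
Acute kidney injury,broad,Hypercreatininaemia
Acute kidney injury,broad,Nephritis
Acute kidney injury,broad,Nephritis allergic
Acute kidney injury,broad,Nephritis interstitial
Acute kidney injury,broad,Tubulointerstitial nephritis
Acute kidney injury,broad,Renal tubular disorder
Acute kidney injury,broad,Renal tubular injury
Acute kidney injury,broad,Urine output decreased
Acute kidney injury,broad,Albuminuria
Acute kidney injury,broad,Protein urine present
Acute kidney injury,broad,Proteinuria
Acute kidney injury,broad,Crystal nephropathy
Acute kidney injury,broad,Myoglobinuria
Acute kidney injury,broad,Rhabdomyolysis
Acute kidney injury,broad,Renal function test abnormal
Acute kidney injury,broad,Renal hypoperfusion
Acute kidney injury,broad,Oedema due to renal disease
Acute kidney injury,broad,Hyperkalaemia
Acute kidney injury,broad,Metabolic acidosis
Acute kidney injury,broad,Urea renal clearance decreased
Acute kidney injury,broad,Blood urea nitrogen increased
Acute kidney injury,broad,Acute phosphate nephropathy
Acute kidney injury,broad,Cystatin C increased
Acute kidney injury,broad,Renal injury
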