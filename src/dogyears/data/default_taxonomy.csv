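diagnosis,pp,os
patent ductus arteriosus,congenital,cardiovascular
ventricular septal defect,congenital,cardiovascular
portosystemic shunt,congenital,hepatic
hydrocephalus,congenital,neurologic
renal dysplasia,congenital,urogenital
cleft palate,congenital,gastrointestinal
degenerative myelopathy,degenerative,neurologic
chronic kidney disease,degenerative,urogenital
osteoarthritis,degenerative,musculoskeletal
intervertebral disc degeneration,degenerative,musculoskeletal
degenerative valve disease,degenerative,cardiovascular
cataract,degenerative,ophthalmologic
cognitive dysfunction,degenerative,neurologic
parvoviral enteritis,infectious,gastrointestinal
leptospirosis,infectious,urogenital
pneumonia,infectious,respiratory
distemper,infectious,neurologic
pyoderma,infectious,dermatologic
sepsis,infectious,hematopoietic
endocarditis,infectious,cardiovascular
arthritis,inflammatory,musculoskeletal
immune-mediated hemolytic anemia,inflammatory,hematopoietic
pancreatitis,inflammatory,gastrointestinal
meningoencephalitis,inflammatory,neurologic
chronic hepatitis,inflammatory,hepatic
glomerulonephritis,inflammatory,urogenital
uveitis,inflammatory,ophthalmologic
atopic dermatitis,inflammatory,dermatologic
diabetes mellitus,metabolic,endocrine
obesity,metabolic,endocrine
hypothyroidism,metabolic,endocrine
hyperadrenocorticism,metabolic,endocrine
hepatic lipidosis,metabolic,hepatic
urate urolithiasis,metabolic,urogenital
lymphoma,neoplastic,hematopoietic
osteosarcoma,neoplastic,musculoskeletal
hemangiosarcoma,neoplastic,cardiovascular
mammary carcinoma,neoplastic,urogenital
mast cell tumor,neoplastic,dermatologic
pulmonary carcinoma,neoplastic,respiratory
hepatocellular carcinoma,neoplastic,hepatic
brain tumor,neoplastic,neurologic
gastric carcinoma,neoplastic,gastrointestinal
insulinoma,neoplastic,endocrine
ocular melanoma,neoplastic,ophthalmologic
rodenticide toxicosis,toxic,hematopoietic
ethylene glycol toxicosis,toxic,urogenital
chocolate toxicosis,toxic,cardiovascular
lead poisoning,toxic,neurologic
mushroom toxicosis,toxic,hepatic
hit by car,traumatic,musculoskeletal
traumatic brain injury,traumatic,neurologic
bite wound,traumatic,dermatologic
diaphragmatic hernia,traumatic,respiratory
hemoabdomen traumatic,traumatic,cardiovascular
thromboembolism,vascular,cardiovascular
stroke,vascular,neurologic
mesenteric torsion,vascular,gastrointestinal
splenic torsion,vascular,hematopoietic
renal infarct,vascular,urogenital
myocardial infarction,vascular,cardiovascular
ill-defined condition,unclassified,unclassified
euthanasia,unclassified,unclassified
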