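# Mini-terminology lexicon: term<TAB>code<TAB>system
# Reconstructed fixture; replace with site terminology as needed.
atrial fibrillation	49436004	SCT
afib	49436004	SCT
a fib	49436004	SCT
paroxysmal atrial fibrillation	282825002	SCT
chronic atrial fibrillation	426749004	SCT
atrial flutter	5370000	SCT
congestive heart failure	42343007	SCT
chf	42343007	SCT
heart failure	42343007	SCT
hypertension	38341003	SCT
htn	38341003	SCT
high blood pressure	38341003	SCT
diabetes mellitus	73211009	SCT
diabetes	73211009	SCT
dm	73211009	SCT
stroke	230690007	SCT
cerebrovascular accident	230690007	SCT
cva	230690007	SCT
transient ischemic attack	230690007	SCT
tia	230690007	SCT
coronary artery disease	53741008	SCT
cad	53741008	SCT
peripheral vascular disease	53741008	SCT
pvd	53741008	SCT
chronic kidney disease	709044004	SCT
ckd	709044004	SCT
renal insufficiency	709044004	SCT
cirrhosis	235856003	SCT
chronic liver disease	235856003	SCT
history of bleeding	131148009	SCT
gi bleed	131148009	SCT
bleeding tendency	131148009	SCT
labile inr	166636006	SCT
unstable inr	166636006	SCT
drug dependence	66214007	SCT
substance abuse	66214007	SCT
alcohol abuse	7200002	SCT
alcoholism	7200002	SCT
etoh abuse	7200002	SCT
mitral stenosis	79619009	SCT
ms of the mitral valve	79619009	SCT
aortic stenosis	60573004	SCT
severe aortic stenosis	60573004	SCT
mechanical prosthetic valve	426263006	SCT
mechanical heart valve	426263006	SCT
pregnant	77386006	SCT
pregnancy	77386006	SCT
infective endocarditis	56819008	SCT
endocarditis	56819008	SCT
hyperthyroidism	34486009	SCT
thyrotoxicosis	34486009	SCT
active gastrointestinal bleeding	74474003	SCT
active major bleeding	74474003	SCT
severe thrombocytopenia	302215000	SCT
thrombocytopenia	302215000	SCT
intracranial hemorrhage	274100004	SCT
prior intracranial hemorrhage	274100004	SCT
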