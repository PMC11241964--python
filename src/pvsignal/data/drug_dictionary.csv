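drug_name,atc_codes
amitriptyline,N06AA09
clomipramine,N06AA04
imipramine,N06AA02
desipramine,N06AA01
nortriptyline,N06AA10
doxepin,N06AA12
trimipramine,N06AA06
dosulepin,N06AA16
maprotiline,N06AA21
opipramol,N06AA05
citalopram,N06AB04
escitalopram,N06AB10
fluoxetine,N06AB03
fluvoxamine,N06AB08
paroxetine,N06AB05
sertraline,N06AB06
moclobemide,N06AG02
phenelzine,N06AF03
tranylcypromine,N06AF04
isocarboxazid,N06AF01
venlafaxine,N06AX16
desvenlafaxine,N06AX23
duloxetine,N06AX21
milnacipran,N06AX17
levomilnacipran,N06AX28
mirtazapine,N06AX11
mianserin,N06AX03
setiptiline,N06AX13
trazodone,N06AX05
bupropion,N06AX12
vortioxetine,N06AX26
agomelatine,N06AX22
tianeptine,N06AX14
nefazodone,N06AX06
vilazodone,N06AX24
reboxetine,N06AX18
hypericum,N06AX25
morphine,N02AA01
opium,N02AA02
hydromorphone,N02AA03
oxycodone,N02AA05
tramadol,N02AX02
tapentadol,N02AX06
fentanyl,N02AB03
alendronate,M05BA04
risedronate,M05BA07
zoledronic acid,M05BA08
ibandronic acid,M05BA06
pamidronic acid,M05BA03
etidronic acid,M05BA01
haloperidol,N05AD01
risperidone,N05AX08
quetiapine,N05AH04
olanzapine,N05AH03
aripiprazole,N05AX12
diazepam,N05BA01
lorazepam,N05BA06
alprazolam,N05BA12
oxazepam,N05BA04
zolpidem,N05CF02
zopiclone,N05CF01
temazepam,N05CD07
melatonin,N05CH01
metformin,A10BA02
atorvastatin,C10AA05
simvastatin,C10AA01
amlodipine,C08CA01
lisinopril,C09AA03
omeprazole,A02BC01
pantoprazole,A02BC02
acetylsalicylic acid,B01AC06
furosemide,C03CA01
warfarin,B01AA03
levothyroxine,H03AA01
paracetamol,N02BE01
ibuprofen,M01AE01
salbutamol,R03AC02
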