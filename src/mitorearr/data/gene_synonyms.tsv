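# Gene-name synonym table, v1.
# Maps names/products found in GenBank mt records to canonical labels.
# Matching is case-insensitive after stripping spaces, hyphens and underscores.
# tRNA-Leu and tRNA-Ser are intentionally absent: their isotypes (L1/L2, S1/S2)
# must be resolved from the codon/anticodon qualifier, never guessed.
cox1	cox1
coi	cox1
co1	cox1
coxi	cox1
cytochromecoxidasesubuniti	cox1
cytochromecoxidasesubunit1	cox1
cytochromeoxidasesubunit1	cox1
cox2	cox2
coii	cox2
co2	cox2
coxii	cox2
cytochromecoxidasesubunitii	cox2
cytochromecoxidasesubunit2	cox2
cytochromeoxidasesubunit2	cox2
cox3	cox3
coiii	cox3
co3	cox3
coxiii	cox3
cytochromecoxidasesubunitiii	cox3
cytochromecoxidasesubunit3	cox3
cytochromeoxidasesubunit3	cox3
cob	cob
cytb	cob
cytochromeb	cob
cytochromebapoenzyme	cob
atp6	atp6
atpase6	atp6
atpsynthasef0subunit6	atp6
atpsynthasesubunit6	atp6
atp8	atp8
atpase8	atp8
atpsynthasef0subunit8	atp8
atpsynthasesubunit8	atp8
nad1	nad1
nd1	nad1
nadhdehydrogenasesubunit1	nad1
nad2	nad2
nd2	nad2
nadhdehydrogenasesubunit2	nad2
nad3	nad3
nd3	nad3
nadhdehydrogenasesubunit3	nad3
nad4	nad4
nd4	nad4
nadhdehydrogenasesubunit4	nad4
nad4l	nad4L
nd4l	nad4L
nadhdehydrogenasesubunit4l	nad4L
nad5	nad5
nd5	nad5
nadhdehydrogenasesubunit5	nad5
nad6	nad6
nd6	nad6
nadhdehydrogenasesubunit6	nad6
rrns	rrnS
12s	rrnS
12srrna	rrnS
12sribosomalrna	rrnS
srrna	rrnS
smallsubunitribosomalrna	rrnS
ssurrna	rrnS
rrnl	rrnL
16s	rrnL
16srrna	rrnL
16sribosomalrna	rrnL
lrrna	rrnL
largesubunitribosomalrna	rrnL
lsurrna	rrnL
trna	trnA
trnaala	trnA
trnr	trnR
trnaarg	trnR
trnn	trnN
trnaasn	trnN
trnd	trnD
trnaasp	trnD
trnc	trnC
trnacys	trnC
trne	trnE
trnaglu	trnE
trnq	trnQ
trnagln	trnQ
trng	trnG
trnagly	trnG
trnh	trnH
trnahis	trnH
trni	trnI
trnaile	trnI
trnk	trnK
trnalys	trnK
trnm	trnM
trnamet	trnM
trnf	trnF
trnaphe	trnF
trnp	trnP
trnapro	trnP
trnt	trnT
trnathr	trnT
trnw	trnW
trnatrp	trnW
trny	trnY
trnatyr	trnY
trnv	trnV
trnaval	trnV
trnl1	trnL1
trnalcun	trnL1
trnaleucun	trnL1
trnl2	trnL2
trnaluur	trnL2
trnaleuuur	trnL2
trns1	trnS1
trnasagn	trnS1
trnaseragn	trnS1
trnasgcu	trnS1
trnaseragc	trnS1
trns2	trnS2
trnasucn	trnS2
trnaserucn	trnS2
trnasuga	trnS2
cr	CR
dloop	CR
atrichregion	CR
atrichregion1	CR
atrichregion2	CR
controlregion	CR
putativecontrolregion	CR
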