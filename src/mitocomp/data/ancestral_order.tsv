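# Ancestral insect (Drosophila yakuba) mitochondrial gene order, linearized at trnI.
# gene	strand
trnI	J
trnQ	N
trnM	J
nad2	J
trnW	J
trnC	N
trnY	N
cox1	J
trnL2	J
cox2	J
trnK	J
trnD	J
atp8	J
atp6	J
cox3	J
trnG	J
nad3	J
trnA	J
trnR	J
trnN	J
trnS1	J
trnE	J
trnF	N
nad5	N
trnH	N
nad4	N
nad4l	N
trnT	J
trnP	N
nad6	J
cob	J
trnS2	J
nad1	N
trnL1	N
rrnL	N
trnV	N
rrnS	N
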