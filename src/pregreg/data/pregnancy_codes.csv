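code,description,category
62...00,Patient pregnant,antenatal
L281.00,Premature rupture of membranes,late_pregnancy
62N8.00,A/N 32 week examination,third_trimester
L20..11,Spontaneous vaginal delivery,delivery
Q4z..15,Stillbirth NEC,stillbirth
L03..00,Ectopic pregnancy,ectopic
L052.11,Medical abortion - complete,top
L04..00,Spontaneous abortion,miscarriage
L05..12,Termination of pregnancy,probable_top
L002.00,Complete hydatidiform mole,molar
L0z..00,Pregnancy with abortive outcome NOS,unspecified_loss
L010.00,Blighted ovum,blighted_ovum
62S7.00,Postnatal examination normal,postnatal
E204.11,Postnatal depression,other_postnatal
L142.11,Premature delivery,preterm
L150.00,Postterm pregnancy,postterm
L210.00,Twin pregnancy,multiple
1513.00,Last menstrual period - first day,lmp
1514.12,Estimated date of delivery,edd
Z22C500,Estimated date of conception,edc
L12..00,Hypertension complicating pregnancy/childbirth/puerperium,pregnancy_related_uncertain
L142.00,Preterm delivery,delivery
L142.00,Preterm delivery,preterm
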