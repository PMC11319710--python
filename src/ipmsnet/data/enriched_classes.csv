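accession,gene,classes
P60711,Actb,actin
O88656,Arpc1b,actin
Q5M7U6,Actr2,actin
Q4V7C7,Actr3,actin
O35889,Afdn,actin
P07150,Anxa1,actin;microtubule
Q07936,Anxa2,actin;keratin_other
Q08163,Cap1,actin
Q9Z1P2,Actn1,actin
Q6GMN2,Baiap2,actin
Q3KR97,Baiap2l1,actin
O89046,Coro1b,actin
Q5XI32,Capzb,actin
P31977,Ezr,actin
P85845,Fscn1,actin
D3ZHA0,Flnc,actin
Q68FP1,Gsn,actin
F1LR10,Lima1,actin
D3ZHV2,Macf1,actin;microtubule
Q64119,Myl6,actin
P18666,Myl12b,actin
Q62812,Myh9,actin
Q62920,Pdlim5,actin
Q9WVC0,Septin7,actin;microtubule
P16086,Sptan1,actin
Q63610,Tpm3,actin
Q05096,Myo1b,actin
Q63357,Myo1d,actin
Q5RKI0,Wdr1,actin
P38650,Dync1h1,microtubule
O35303,Dnm1l,microtubule
Q91Y81,Septin2,microtubule;actin
Q9QZR6,Septin9,microtubule;actin
P68370,Tuba1a,microtubule
Q5XIF6,Tuba4a,microtubule
P35213,Ywhab,keratin_other
P62260,Ywhae,keratin_other
P68511,Ywhah,keratin_other
P61983,Ywhag,keratin_other
P04764,Eno1,keratin_other
P14669,Anxa3,keratin_other
P55260,Anxa4,keratin_other
P14668,Anxa5,keratin_other
Q9R1T1,Banf1,keratin_other
Q9WTT7,Bzw2,keratin_other
Q9WU82,Ctnnb1,keratin_other
Q8CFN2,Cdc42,keratin_other
Q63532,Sprr1a,keratin_other
Q5M9G3,Caprin1,keratin_other
Q7TQ20,Dnajc2,keratin_other
Q62940,Nedd4,keratin_other
Q641Z6,Ehd1,keratin_other
P68101,Eif2s1,keratin_other
Q4G061,Eif3b,keratin_other
Q6AYK8,Eif3d,keratin_other
Q641X8,Eif3e,keratin_other
Q5RK09,Eif3g,keratin_other
B2GUV7,Eif5b,keratin_other
P08699,Lgals3,keratin_other
P04897,Gnai2,keratin_other
P06761,Hspa5,keratin_other
P42930,Hspb1,keratin_other
P82995,Hsp90aa1,keratin_other
P34058,Hsp90ab1,keratin_other
Q64632,Itgb4,keratin_other
Q7TQM5,Kprp,keratin_other
P19804,Nme2,keratin_other
P23606,Tgm1,keratin_other
B4F7E8,Niban2,keratin_other
P50399,Gdi2,keratin_other
Q6RUV5,Rac1,keratin_other
B3GNI6,Septin11,keratin_other
Q2LAP6,Tes,keratin_other
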