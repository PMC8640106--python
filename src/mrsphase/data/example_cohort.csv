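subject_id,diagnosis,mimics_usual,premonitory,a1_time,a1_vrs,a2_time,a2_vrs,unilateral,pulsating,aggravated,nausea,vomiting,photophobia,phonophobia,treated,treatment_drug
P2,migraine,1,1,210,6,240,8,1,0,1,1,0,1,0,1,paracetamol-caffeine
P3,migraine,1,1,195,5,270,7,1,1,1,1,0,0,0,1,zolmitriptan
P4,migraine,1,1,210,4,300,6,0,1,1,0,0,1,1,0,
P5,migraine,1,1,225,5,300,7,1,0,1,0,0,1,0,1,excedrin
P7,migraine,1,1,330,4,,,0,0,1,0,0,1,1,0,
P8,migraine,1,1,225,5,,,1,1,1,1,0,1,0,0,
P9,migraine,1,1,135,3,225,6,0,0,1,1,0,1,0,1,eletriptan
P10,migraine,1,1,60,3,150,10,0,0,0,0,0,0,0,1,sumatriptan-injection
P12,migraine,1,1,300,3,,,1,0,1,1,0,1,0,1,sumatriptan
P13,migraine,1,1,90,5,300,9,1,1,1,0,0,0,1,1,sumatriptan
P14,migraine,0,1,345,7,,,0,1,1,1,0,1,1,1,paracetamol-naproxen
P16,migraine,1,1,195,2,300,5,1,1,1,0,0,1,0,1,almotriptan
P17,migraine,1,0,300,3,,,0,0,0,0,0,0,0,1,sumatriptan
P18,migraine,1,1,45,4,300,8,1,1,1,1,1,0,0,1,sumatriptan-injection
P19,migraine,1,1,270,6,,,1,0,1,0,0,1,1,1,analgesic
P20,migraine,1,0,150,3,300,7,1,1,0,0,0,0,0,1,sumatriptan
P21,migraine,1,1,135,4,285,7,0,0,0,0,0,1,0,1,sumatriptan-injection
P22,migraine,1,1,45,2,150,5,1,1,0,1,0,0,0,0,
P23,migraine,1,1,45,5,135,8,0,0,1,0,0,1,0,1,sumatriptan-injection
P24,migraine,1,1,240,4,300,6,0,1,0,0,0,0,0,1,eletriptan
P25,migraine,1,1,240,5,300,7,1,1,0,0,0,0,0,1,rizatriptan
N1,migraine,0,0,300,2,,,0,0,0,0,0,0,0,0,
N2,migraine,0,0,300,1,,,0,0,0,0,0,0,0,0,
N3,migraine,0,0,300,0,,,0,0,0,0,0,0,0,0,
C1,control,0,0,90,2,,,0,0,0,0,0,0,0,0,
C2,control,0,0,90,1,,,0,0,0,0,0,0,0,0,
C3,control,0,0,90,3,,,0,0,0,0,0,0,0,0,
C4,control,0,0,90,2,,,0,0,0,0,0,0,0,0,
C5,control,0,0,90,1,,,0,0,0,0,0,0,0,0,
C6,control,0,0,90,2,,,0,0,0,0,0,0,0,0,
C7,control,0,0,270,5,,,0,0,0,0,0,0,0,0,
C8,control,0,0,300,0,,,0,0,0,0,0,0,0,0,
C9,control,0,0,300,0,,,0,0,0,0,0,0,0,0,
C10,control,0,0,300,0,,,0,0,0,0,0,0,0,0,
C11,control,0,0,300,0,,,0,0,0,0,0,0,0,0,
C12,control,0,0,300,0,,,0,0,0,0,0,0,0,0,
C13,control,0,0,300,0,,,0,0,0,0,0,0,0,0,
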