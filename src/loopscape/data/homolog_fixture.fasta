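>hom_0
DAPAVHARGYGSKSNSCGRGDSPAS
>hom_1
DAPAVHARGYGSKSNSCGRGDSPAS
>hom_2
DAPAVHARGYGSKSNSCGRGDSPAS
>hom_3
DAPAVHARGYGSKSNSCGRGDSPAS
>hom_4
DAPAVHARGYGSKSNSCGRGDSPAS
>hom_5
DAPAVHARGYGSKSNSCGRGDSPAS
>hom_6
DAPAVHARGYGSKSNSCGRGDSPAS
>hom_7
DAPAVHARGYGSKSNSCGRGDSPAS
>hom_8
DAPAVHARGYGSKSNSCGRGDSPAS
>hom_9
DDPA-TARGYGSKSNSTGRGDSYAS
>hom_10
DDPA-TARGYGSKSNSTGRGDSYAS
>hom_11
DDPA-TARGYGSKSNSTGRGDSYAS
>hom_12
DDPA-TARGYGSKSNSTGRGDSYAS
>hom_13
DAPAVTARGYG-KSNSTGRGDSIAS
>hom_14
DAPAVTARGYG-KSNSTGRGDSIAS
>hom_15
DAPAVTARGYG-KSNSTGRGDSIAS
>hom_16
DAPAVTARGYG-KSNSTGRGDSIAS
>hom_17
DAPAV-ARGYGSNSNSTGRGPSPAD
>hom_18
DYPAVTARGYGSNSNSSGRGDSPAS
>hom_19
DAPAVSARGYGSKSNSTGRGDSPAS
>hom_20
DAPAVTARGGGSKSNSTGVGFSPAS
>hom_21
DSPAVTERGYGSKSNSTGRGDSPAS
>hom_22
DAPAVTARGSGSKSNGTGRGDSPAS
>hom_23
DAPAVTARGYGLKSNSTGRGDSEAF
>hom_24
DAPAVTARGYGSKSNETGRGDSPAS
>hom_25
DAPAV-ARLCGSKWNSTDRGCSPAS
>hom_26
DAPAVTARGYGSKSNSTMRGDSPAS
>hom_27
DAPAVTARGYGSKSNSGGRGDSPAG
>hom_28
DAPAVYARDYPSLSNSTGRGDSPAS
>hom_29
DAPAVTARHYGSKANSTGRGDSPAW
>hom_30
DAPAVTARGYGSKSASTGRGDSPAS
>hom_31
D-PAVTARGYGSKSNSTGRGDSPCS
>hom_32
-VPAKTARGYGSKSNSTGRGDSPAS
>hom_33
DAPAVTARGLGSKSNSDGRTDSPAS
>hom_34
DAPAVTARGYSSKSESTGRGDSPAS
>hom_35
DAPAVTADGY-SKSNSRGRGDSPAS
>hom_36
DAPAVTARGFGSKSNSTGRGDSPAS
>hom_37
DAPAQTARGYGSKSNSTGWGDSPAS
>hom_38
DAPAVFARGYGSFINSTGRGDSPAC
>hom_39
QAPAVTARGYGSGSNLTGRGDSPAS
>hom_40
FAPAVTARGYDLKSNSTGRGDIPAS
>hom_41
DAPAVTARGYGSFSNVTGRGDSSAS
>hom_42
DAPAPTARGYGSKSNSTGRGDSPAS
>hom_43
DAPVVQARGYGSKSNSTGRGDSPAS
>hom_44
DAPDVTA-GNFSKSNSTGKGDSPAS
>hom_45
DAGAVTARGYGSKSNSTGRGDSPAS
>hom_46
DAPAVTARGYGSKSWSTGRGDSPAS
>hom_47
DAPAVTADGYGSKENSTGRCDSPFS
>hom_48
DAPQVTARGYGSKSNSTGRVDYPAS
>hom_49
DAPAVTHRGYGSKSNSTGRGDSPAS
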