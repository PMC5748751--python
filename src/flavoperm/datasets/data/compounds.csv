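id,name,subclass,R3,R5,R6,R7,R8,R2p,R3p,R4p,R5p,is_glycoside
1,Flavone,flavone,H,H,H,H,H,H,H,H,H,false
2,Tangertin,flavone,H,OMe,OMe,OMe,OMe,H,H,OMe,H,false
3,Wogonin,flavone,H,OH,H,OH,OMe,H,H,H,H,false
4,Baicalein,flavone,H,OH,OH,OH,H,H,H,H,H,false
5,Luteolin,flavone,H,OH,H,OH,H,H,OH,OH,H,false
6,Apigenin,flavone,H,OH,H,OH,H,H,H,OH,H,false
7,Chrysin,flavone,H,OH,H,OH,H,H,H,H,H,false
8,Schaftoside,flavone,H,OH,Cglc,OH,Carb,H,H,OH,H,true
9,Galangin,flavonol,OH,OH,H,OH,H,H,H,H,H,false
10,Quercetin,flavonol,OH,OH,H,OH,H,H,OH,OH,H,false
11,Morin,flavonol,OH,OH,H,OH,H,OH,H,OH,H,false
12,Kaempferol,flavonol,OH,OH,H,OH,H,H,H,OH,H,false
13,Kaempferide,flavonol,OH,OH,H,OH,H,H,H,OMe,H,false
14,Myricetin,flavonol,OH,OH,H,OH,H,H,OH,OH,OH,false
15,Isorhamnetin,flavonol,OH,OH,H,OH,H,H,OMe,OH,H,false
16,Quercitrin,flavonol,Orha,OH,H,OH,H,H,OH,OH,H,true
17,Rutin,flavonol,ORG,OH,H,OH,H,H,OH,OH,H,true
18,Hesperetin,flavanone,H,OH,H,OH,H,H,OH,OMe,H,false
19,Naringenin,flavanone,H,OH,H,OH,H,H,H,OH,H,false
20,Naringin,flavanone,H,OH,H,ONG,H,H,H,OH,H,true
21,Liquiritigenin,flavanone,H,H,H,OH,H,H,H,OH,H,false
22,Taxifolin,flavanone,OH,OH,H,OH,H,H,OH,OH,H,false
23,Formononetin,isoflavone,-,H,OH,H,H,H,OMe,H,H,false
24,Puerarin,isoflavone,-,H,H,OH,Cglc,H,H,OH,H,true
25,Glycitein,isoflavone,-,H,OMe,OH,H,H,H,OH,H,false
26,Daidzein,isoflavone,-,H,H,OH,H,H,H,OH,H,false
27,Genistein,isoflavone,-,OH,H,OH,H,H,H,OH,H,false
28,Biochanin A,isoflavone,-,OH,H,OH,H,H,H,OMe,H,false
29,Isoliquiritigenin,chalcone,OH,OH,-,-,-,H,H,OH,H,false
30,Neohesperidin dihydrochalcone,dihydrochalcone,NG,OH,-,-,-,H,OH,OMe,H,true
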