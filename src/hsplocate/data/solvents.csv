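cas,name,synonyms,smiles,dD,dP,dH
109-99-9,tetrahydrofuran,THF;oxolane;tetrahydrofuran (THF),C1CCOC1,16.8,5.7,8.0
141-78-6,ethyl acetate,EtOAc;ethyl ethanoate,CCOC(C)=O,15.8,5.3,7.2
67-66-3,chloroform,trichloromethane,ClC(Cl)Cl,17.8,3.1,5.7
67-64-1,acetone,propan-2-one;2-propanone,CC(C)=O,15.5,10.4,7.0
123-91-1,"1,4-dioxane",dioxane;p-dioxane,C1COCCO1,19.0,1.8,7.4
60-29-7,diethyl ether,ethoxyethane;Et2O,CCOCC,19.0,7.4,4.1
107-06-2,"1,2-dichloroethane",DCE;ethylene dichloride,ClCCCl,14.5,2.9,5.1
1330-20-7,xylene,xylenes;dimethylbenzene,Cc1ccccc1C,17.6,1.0,3.1
108-88-3,toluene,methylbenzene;toluol,Cc1ccccc1,18.0,1.4,2.0
67-63-0,isopropanol,IPA;2-propanol;propan-2-ol,CC(C)O,15.8,6.1,16.4
110-54-3,hexane,n-hexane,CCCCCC,14.9,0.0,0.0
64-17-5,ethanol,EtOH;ethyl alcohol,CCO,15.8,8.8,19.4
75-05-8,acetonitrile,MeCN;methyl cyanide,CC#N,15.3,18.0,6.1
7732-18-5,water,deionized water,O,15.5,16.0,42.3
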