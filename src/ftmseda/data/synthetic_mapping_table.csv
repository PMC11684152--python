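formula,database,entry_type,entry_id,entry_name
C6H12O6,KEGG,compound,C00031,D-Glucose
C6H12O6,KEGG,compound,C00095,D-Fructose
C6H12O6,KEGG,compound,C00124,D-Galactose
C6H12O6,KEGG,compound,C00159,D-Mannose
C6H12O6,KEGG,compound,C00181,Synthetic hexose A
C6H12O6,KEGG,compound,C00221,Synthetic hexose B
C6H12O6,KEGG,compound,C00267,Synthetic hexose C
C6H12O6,KEGG,pathway,map00010,Glycolysis
C6H12O6,KEGG,pathway,map00052,Galactose metabolism
C6H12O6,MetaCyc,compound,GLC,Glc
C5H9NO4,KEGG,compound,C00025,L-Glutamate
C5H9NO4,KEGG,reaction,R00243,Glutamate dehydrogenase reaction
C5H9NO4,MetaCyc,pathway,GLUTSYN-PWY,Glutamate biosynthesis
C10H14N2,KEGG,compound,C00745,Nicotine
C18H36O2,KEGG,compound,C01530,Octadecanoate
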