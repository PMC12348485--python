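compound_id,name,formula,class,smiles,source
arginine,Arginine,C6H14N4O2,other,NC(CCCNC(N)=N)C(O)=O,amino acid
glutathione,Glutathione,C10H17N3O6S,other,,tripeptide
coclaurine,Coclaurine,C17H19NO3,alkaloid,,benzylisoquinoline
armepavine,Armepavine,C19H23NO3,alkaloid,,benzylisoquinoline
feruloyltyramine,N-Feruloyltyramine,C18H19NO4,phenylpropanoid,,hydroxycinnamic acid amide
xylopine,Xylopine,C18H17NO3,alkaloid,,aporphine
pheophytin_a,Pheophytin A,C55H74N4O5,other,,chlorophyll degradation product
kaempferol,Kaempferol,C15H10O6,flavonoid,,flavonol
catechin,Catechin,C15H14O6,flavonoid,,flavan-3-ol
taxifolin,Taxifolin,C15H12O7,flavonoid,,dihydroflavonol
methyladenosine_5o,5'-O-Methyladenosine,C11H15N5O4,other,,nucleoside
palmitic_acid,Palmitic acid,C16H32O2,fatty acid,CCCCCCCCCCCCCCCC(O)=O,saturated C16
oleic_acid,Oleic acid,C18H34O2,fatty acid,,monounsaturated C18
linolenic_acid,Linolenic acid,C18H30O2,fatty acid,,polyunsaturated C18
anisic_acid,Anisic acid,C8H8O3,phenolic acid,COc1ccc(cc1)C(O)=O,methoxybenzoic acid
myricetin_3_glucoside,Myricetin 3-O-glucoside,C21H20O13,flavonoid,,flavonol glycoside
astragalin,Astragalin,C21H20O11,flavonoid,,kaempferol 3-O-glucoside
rutin,Rutin,C27H30O16,flavonoid,,quercetin 3-O-rutinoside
syringetin_3_glucoside,Syringetin 3-O-glucoside,C23H24O13,flavonoid,,flavonol glycoside
vitexin,Vitexin,C21H20O10,flavonoid,,apigenin 8-C-glucoside
luteolin_7_rutinoside,Luteolin 7-O-rutinoside,C27H30O15,flavonoid,,flavone glycoside
schaftoside,Schaftoside,C26H28O14,flavonoid,,apigenin C-glycoside
epitaxifolin,Epitaxifolin,C15H12O7,flavonoid,,taxifolin epimer
lanuginosine,Lanuginosine,C18H11NO4,alkaloid,,oxoaporphine
pronuciferine,Pronuciferine,C19H21NO3,alkaloid,,proaporphine
norcoclaurine,Norcoclaurine,C16H17NO3,alkaloid,,benzylisoquinoline
norarmepavine,N-Norarmepavine,C18H21NO3,alkaloid,,benzylisoquinoline
methylisococlaurine,N-Methylisococlaurine,C18H21NO3,alkaloid,,benzylisoquinoline
methylcoclaurine,N-Methylcoclaurine,C18H21NO3,alkaloid,,benzylisoquinoline
liensinine,Liensinine,C37H42N2O6,alkaloid,,bisbenzylisoquinoline
isoliensinine,Isoliensinine,C37H42N2O6,alkaloid,,bisbenzylisoquinoline
neferine,Neferine,C38H44N2O6,alkaloid,,bisbenzylisoquinoline
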