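name,role,formula
benzylamine,amine,C7H9N
4-methylbenzylamine,amine,C8H11N
p-methoxybenzylamine,amine,C8H11NO
4-chlorobenzylamine,amine,C7H8ClN
4-tert-butylbenzylamine,amine,C11H17N
cyclohexanecarboxaldehyde,aldehyde,C7H12O
3-cyclohexylpropanal,aldehyde,C9H16O
valeraldehyde,aldehyde,C5H10O
isovaleraldehyde,aldehyde,C5H10O
cyclopentanecarboxaldehyde,aldehyde,C6H10O
Boc-glycine,acid,C7H13NO4
Boc-proline,acid,C10H17NO4
Boc-N-methyl-L-valine,acid,C11H21NO4
Boc-L-asparagine,acid,C9H16N2O5
Boc-L-beta-homoleucine,acid,C12H23NO4
Boc-L-methionine,acid,C10H19NO4S
Boc-L-beta-homoglutamine,acid,C11H20N2O5
Boc-L-beta-homomethionine,acid,C11H21NO4S
Boc-L-phenylalanine,acid,C14H19NO4
Boc-N-alpha-N-epsilon-formyl-L-lysine,acid,C12H22N2O5
Boc-N-methyl-L-phenylalanine,acid,C15H21NO4
Boc-O-methyl-L-tyrosine,acid,C15H21NO5
cyclohexyl isocyanide,isocyanide,C7H11N
ethyl isocyanoacetate,isocyanide,C5H7NO2
benzyl isocyanide,isocyanide,C8H7N
2-naphthyl isocyanide,isocyanide,C11H7N
methyl isocyanoacetate,isocyanide,C4H5NO2
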