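disease,phenotype,penetrance_pct,group_id
Down syndrome,Short face,100,g1
Down syndrome,Upward slanting eyes,100,g2
Down syndrome,Epicanthus,100,g3
Down syndrome,Brushfield spots,100,g4
Down syndrome,Low-set ears,100,g5
Down syndrome,Small ears,100,g6
Down syndrome,Flattened nose,100,g7
Down syndrome,Small mouth,100,g8
Down syndrome,Protruding tongue,100,g9
Acromegaly,Forehead bulge,100,g1
Acromegaly,Prominent jaw,100,g2
Acromegaly,Prominent zygomatic arch,100,g3
Acromegaly,Deep nasolabial folds,100,g4
Acromegaly,Enlarged nose,100,g5
Acromegaly,Enlarged brow,100,g6
Acromegaly,Enlarged ear,100,g7
Acromegaly,Enlarged lip,100,g8
Cornelia de Lange syndrome,Short face,82.7,g1
Cornelia de Lange syndrome,Small jaw,82.7,g2
Cornelia de Lange syndrome,Arched eyebrows,82.7,g3
Cornelia de Lange syndrome,Joined eyebrows,82.7,g4
Cornelia de Lange syndrome,Short nose,82.7,g5
Cornelia de Lange syndrome,Forward nostril,82.7,g6
Cornelia de Lange syndrome,Long philtrum,82.7,g7
Cornelia de Lange syndrome,Thin upper lip,82.7,g8
Cornelia de Lange syndrome,Upturned corners of the mouth,82.7,g9
Angelman syndrome,Narrow bifrontal diameter,100,g1
Angelman syndrome,Huge jaw,100,g2
Angelman syndrome,Almond-shaped palpebral fissures,100,g3
Angelman syndrome,Narrow nasal bridge,100,g4
Angelman syndrome,Thin upper lip,100,g5
Angelman syndrome,Protruding tongue,100,g6
Cushing's syndrome,Red face,100,g1
Cushing's syndrome,Full moon face,100,g2
Cushing's syndrome,Acne,100,g3
Cushing's syndrome,Excessive hair,100,g4
Cushing's syndrome,Chemosis conjunctiva,100,g5
Fetal alcohol spectrum disorders,Small head,100,g1
Fetal alcohol spectrum disorders,Short palpebral fissures,100,g2
Fetal alcohol spectrum disorders,Smooth philtrum,100,g3
Fetal alcohol spectrum disorders,Thin vermilion border of the upper lip,100,g4
Turner syndrome,Small jaw,56,g1
Turner syndrome,Epicanthus,56,g2
Turner syndrome,Ptosis,56,g3
Turner syndrome,Ocular hypertelorism,56,g4
Turner syndrome,Low-set ears,56,g5
Turner syndrome,Multiple facial nevi,56,g6
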