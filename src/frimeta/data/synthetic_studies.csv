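study_id,disease,tp,fp,fn,tn,fri,training_n,resolution_px,model_class,control_type,n_diseases,validation,excl_flags
s01,Down syndrome,146,8,7,53,9.0,30,10000,non_deep_learning,healthy,1,internal,
s02,Down syndrome,96,9,2,101,9.0,150,,deep_learning,other_diseases,1,internal,unclear_reference
s03,Down syndrome,74,16,6,155,9.0,1200,160000,unreported,other_diseases,1,external,unclear_model;external_validation
s04,Acromegaly,27,16,1,200,8.0,49,22500,non_deep_learning,healthy,1,internal,
s05,Acromegaly,35,7,5,43,8.0,180,48400,deep_learning,other_diseases,1,internal,unclear_sampling
s06,Acromegaly,36,9,6,105,8.0,620,1500000,non_deep_learning,other_diseases,1,external,external_validation
s07,Acromegaly,56,10,1,96,8.0,2100,,deep_learning,other_diseases,1,external,external_validation
s08,Cornelia de Lange syndrome,85,13,9,150,7.443,90,10000,deep_learning,healthy,1,internal,
s09,Cornelia de Lange syndrome,217,5,17,85,7.443,310,,unreported,other_diseases,1,internal,unclear_model;unclear_reference
s10,Cornelia de Lange syndrome,137,1,13,49,7.443,1500,90000,deep_learning,healthy,1,external,external_validation
s11,Angelman syndrome,73,18,16,137,6.0,260,,unreported,other_diseases,1,internal,unclear_model;unclear_sampling
s12,Cushing's syndrome,23,7,10,82,5.0,60,14400,non_deep_learning,healthy,1,internal,
s13,Cushing's syndrome,54,17,8,150,5.0,410,,unreported,other_diseases,1,internal,unclear_model;unclear_reference
s14,Fetal alcohol spectrum disorders,60,9,74,109,4.0,870,250000,deep_learning,other_diseases,1,external,external_validation
s15,Turner syndrome,108,3,60,20,3.36,130,25600,non_deep_learning,healthy,1,internal,unclear_sampling
s16,Turner syndrome,95,5,41,120,3.36,3465,,deep_learning,other_diseases,1,external,external_validation
s17,multiple,162,0,18,59,,520,40000,unreported,healthy,2,internal,unclear_model;unclear_reference
s18,multiple,19,5,0,74,,980,16900,non_deep_learning,healthy,3,internal,unclear_sampling
s19,multiple,182,2,10,26,,1050,640000,non_deep_learning,other_diseases,5,external,external_validation
s20,multiple,125,7,7,82,,2600,120000,non_deep_learning,healthy,10,external,external_validation
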