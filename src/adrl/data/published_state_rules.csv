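cohort,state,ADAS13,RAVLT_IMMEDIATE,RAVLT_LEARNING,AGE,CDRSB,MOCA,FDG
WHOLE,S0,"(,19.5]","(,22.5]",,"(,77]",,,
WHOLE,S1,"(,19.5]","(,22.5]",,"[78,)",,,
WHOLE,S2,"(,19.5]","(22.5,)",,,"(,1.8]",,
WHOLE,S3,"(,19.5]","(22.5,)",,,"(1.8,]",,
WHOLE,S4,"(19.5,25.8]",,,,"(,1.8]","(,19.5]",
WHOLE,S5,"(19.5,25.8]",,,,"(1.8,]","(,19.5]",
WHOLE,S6,"(19.5,25.8]",,,,,"(19.5,21.5]",
WHOLE,S7,"(19.5,25.8]",,,,,"(21.5,]",
WHOLE,S8,"(25.8,36.2]",,,,"(,1.8]","(,19.5]",
WHOLE,S9,"(25.8,36.2]",,,,"(1.8,4.2]","(,19.5]",
WHOLE,S10,"(25.8,36.2]",,,,"(4.2,]","(,19.5]",
WHOLE,S11,"(36.2,42.7]",,,,,,
WHOLE,S12,"(42.7,)",,,,,,
AD,S13,"(,18.5]",,"(,1.5]",,,,
AD,S14,"(,18.5]",,"(1.5,)",,,,
AD,S15,"(18.5,25.2]",,,,,"(,21.5]","(,6]"
AD,S16,"(18.5,25.2]",,,,,"(,21.5]","(6,)"
AD,S17,"(18.5,25.2]",,,,,"(21.5,)",
AD,S18,"(25.2,35.8)",,,,"(,3.2]",,
AD,S19,"(25.2,35.8)",,,,"(3.2,)",,"(,5]"
AD,S20,"(25.2,35.8)",,,,"(3.2,)",,"(5,)"
AD,S21,"(35.8,)",,,,,,
AD_HTN,S22,"(,17.5]",,,,,"(,20.5]",
AD_HTN,S23,"(17.5,22.2]",,,,,"(,20.5]",
AD_HTN,S24,"(,22.2]",,,,,"(20.5,)",
AD_HTN,S25,"(22.2,25.2]",,,,,"(,13.5]",
AD_HTN,S26,"(22.2,25.2]",,,,,"(13.5,)",
AD_HTN,S27,"(25.2,31.2]",,,,"(,1.8]",,
AD_HTN,S28,"(25.2,31.2]",,,,"(1.8,3.2]",,
AD_HTN,S29,"(25.2,31.2]",,,,"(3.2,)",,
AD_HTN,S30,"(31.2,41.8]",,,"(,75]",,,
AD_HTN,S31,"(31.2,41.8]",,,"(75,)",,,
AD_HTN,S32,"(41.8,)",,,,,,
AD_HTN,S33,"(25.2,31.2]",,,,"(,3.2]",,
AD_DEP,S34,"(,22.2]",,,,"(,3.75]","(,20.5]",
AD_DEP,S35,"(,22.2]",,,,"(3.75,)","(,20.5]",
AD_DEP,S36,"(,22.2]",,,,,"(20.5,)",
AD_DEP,S37,"(22.2,25.2]",,,,"(,3.75]","(,21.5]",
AD_DEP,S38,"(22.2,25.2]",,,,"(3.75,)","(,21.5]",
AD_DEP,S39,"(25.2,35.8]",,,,"(,3.25]",,
AD_DEP,S40,"(25.2,35.8]",,,,"(3.25,)",,
AD_DEP,S41,"(35.8,)",,,,,"(,12.5]",
AD_DEP,S41,"(35.8,)",,,,,"(12.5,)",
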