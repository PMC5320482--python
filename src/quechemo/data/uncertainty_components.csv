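analyte,u1,u2,u3,u4,uc_printed,uexp_printed
"2,4-D",0.0015,0.0302,0.0035,0.0298,0.0425,8.5
carbendazim,0.0015,0.0205,0.0048,0.0213,0.0299,5.9
thiabendazole,0.0015,0.0232,0.0045,0.0303,0.0385,7.7
iprodione,0.0021,0.0027,0.0027,0.0371,0.0374,7.5
prochloraz,0.0015,0.0285,0.0059,0.0306,0.0423,8.4
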