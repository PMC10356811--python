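dataset,raw_symbol,unified_code,kind
synth,N,N,beat
synth,V,PVC,beat
synth,A,PAC,beat
synth,N,SINUS,rhythm
synth,AFIB,AFIB,rhythm
synth,AFL,AFL,rhythm
synth,ST,STACH,rhythm
synth,SBR,SBRAD,rhythm
synth,SVTA,SVTA,rhythm
synth_rec,N,SINUS,rhythm
synth_rec,AFIB,AFIB,rhythm
synth_rec,AFL,AFL,rhythm
synth_rec,ST,STACH,rhythm
synth_rec,SBR,SBRAD,rhythm
synth_rec,SVTA,SVTA,rhythm
mitbih_ar,N,N,beat
mitbih_ar,L,LBBB,beat
mitbih_ar,R,RBBB,beat
mitbih_ar,V,PVC,beat
mitbih_ar,A,PAC,beat
mitbih_ar,F,FUSION,beat
mitbih_ar,/,PACED,beat
mitbih_ar,Q,UNKNOWN,beat
mitbih_ar,(N,SINUS,rhythm
mitbih_ar,(AFIB,AFIB,rhythm
mitbih_ar,(AFL,AFL,rhythm
mitbih_ar,(SVTA,SVTA,rhythm
mitbih_ar,AFIB,AFIB,rhythm
arr10000,AF,AFIB,rhythm
arr10000,SR,SINUS,rhythm
arr10000,ST,STACH,rhythm
arr10000,SB,SBRAD,rhythm
arr10000,SVT,SVTA,rhythm
arr10000,AFL,AFL,rhythm
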