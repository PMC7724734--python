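species,locality,infected,screened
Aedeomyia catastica,BA,0,1
Aedes aegypti,BN,0,1
Aedes aegypti,U,0,13
Aedes albolineatus,M,0,3
Aedes albopictus,DF,6,10
Aedes albopictus,KR,6,10
Aedes albopictus,KJ,3,6
Aedes albopictus,M,6,11
Aedes annandalei,KR,3,4
Aedes annandalei,M,8,9
Aedes nr. fumidus,SBL,6,10
Aedes gardnerii,M,1,1
Aedes malayensis,DF,1,2
Aedes malayensis,KR,13,16
Aedes malayensis,KJ,0,2
Anopheles barbirostris complex,DF,0,2
Anopheles barbirostris complex,M,0,2
Anopheles lesteri,KJ,0,2
Anopheles sinensis,BA,0,12
Armigeres kesseli,KR,3,3
Coquillettidia crassipes,DF,2,2
Coquillettidia crassipes,KR,6,7
Coquillettidia crassipes,KJ,4,4
Culex (Lophoceramyia) spp.,KR,0,1
Culex (Lophoceramyia) spp.,KJ,0,2
Culex (Lophoceramyia) spp.,M,1,9
Culex (Lophoceramyia) spp.,T,0,2
Culex bitaeniorhynchus,KR,0,1
Culex brevipalpis,DF,0,1
Culex brevipalpis,M,0,2
Culex nigropunctatus,KJ,0,1
Culex nigropunctatus,M,0,2
Culex pseudovishnui,KR,11,12
Culex pseudovishnui,M,4,4
Culex pseudovishnui,SBG,3,5
Culex pseudovishnui,SBL,1,1
Culex quinquefasciatus,BA,5,8
Culex sitiens,SBL,2,4
Culex sp.,M,0,2
Culex tritaeniorhynchus,KJ,2,5
Culex tritaeniorhynchus,SBL,0,1
Culex tritaeniorhynchus,T,0,1
Culex vishnui,M,0,2
Culex vishnui,T,0,3
Malaya genurostris,BB,2,4
Malaya genurostris,KR,0,1
Malaya genurostris,KJ,4,13
Malaya genurostris,SBG,0,1
Mansonia dives,M,0,2
Mansonia indiana,KJ,3,3
Mimomyia luzonensis,KJ,0,1
Tripteroides sp.,KR,0,7
Tripteroides sp.,M,1,2
Uranotaenia obscura,DF,2,4
Uranotaenia obscura,M,2,2
Uranotaenia obscura,RR,1,1
Uranotaenia sp.,DF,1,2
Uranotaenia trilineata,M,1,1
Verrallina butleri,KJ,1,1
Verrallina sp.,RR,1,5
Zeugnomyia gracilis,DF,1,2
Zeugnomyia gracilis,M,1,13
Zeugnomyia gracilis,RR,1,4
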