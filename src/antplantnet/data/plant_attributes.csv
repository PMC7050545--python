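species,code,efn_distribution,habitat,cover
Cordia spinescens,CorSpi,D,S,38.833
Turnera ulmifolia,TurUlm,C,O,6.66
Crotalaria indica,CrotIn,C,O,12.38
Cedrela odorata,CedOdo,D,S,36.143
Callicarpa acuminata,CallAc,D,B,68.797
Caesalpinia crista,CaeCri,C,O,27.15
Bidens pilosa,BidPil,C,S,27.95
Canavalia rosea,CanRos,C,O,76.057
Calopogonium caeruleum,CalCae,C,O,16.85
Terminalia catappa,TerCat,C,S,0.35
Senna occidentalis,SenOcc,C,S,3.717
Opuntia stricta,OpuStri,D,O,64.35
Hibiscus tiliaceus,HibTill,C,O,2.4
Amphilophium paniculatum,AmphPa,D,O,17.55
Ipomoea pescaprae,IpoPes,C,O,49.1
Conocarpus erectus,ConEre,C,S,16.383
Ficus obtusifolia,FicObt,C,S,8.15
Cornutia grandiflora,CorGra,D,O,2.5
Macroptilium atropurpureum,MacAtr,C,O,16.3
Cissus rhombifolia,CisRho,C,O,3.55
Ipomoea sp.,IpoSp.,C,S,12.167
Mansoa hymenaea,ManHym,C,S,16.3
Tabebuia rosea,TabRos,D,S,6.66
Acacia macracantha,AcaMac,C,B,2.75
Trichilia havanensis,TriHav,C,S,28.33
Arundo donax,AruDon,C,O,151.66
Petrea volubilis,PetVol,D,O,74.1
Chamaecrista chamaecristoides,ChaCha,C,O,32.4
Iresine celosia,IreCel,C,O,16.55
Cordia dentata,CorDen,D,S,3.615
Bunchosia lindeliana,BunLin,C,S,1.7
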