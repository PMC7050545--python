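species,code,invasive,dominance,head_length
Camponotus planatus,CamPla,NO,C,1.198
Camponotus mucronatus,CamMu,NO,C,1.418
Camponotus atriceps,CamAt,NO,C,1.946
Azteca sp. 1,AztSp,NO,A,1.471
Paratrechina longicornis,ParLo,INV,E,0.638
Tetramorium spinosum,TetSpi,INV,E,0.968
Cephalotes minutus,CepMin,NO,D,1.155
Dorymyrmex bicolor,DorBi,NO,A,0.973
Pseudomyrmex gracilis,PseGra,NO,F,1.738
Monomorium cyaneum,MonCy,NO,B,0.482
Camponotus mucronatus hirsutinasus,CamHi,NO,C,1.076
Pachycondyla villosa,PachVi,NO,F,2.880
Forelius analis,ForAna,NO,A,0.631
Crematogaster brevispinosa,CreBre,NO,B,1.031
Pheidole sp.,PheSp,NO,B,0.553
Solenopsis geminata,SolGe,INV,D,0.684
Wassmannia auropunctata,WasAu,INV,D,0.479
Pseudomyrmex ejectus,PseEje,NO,F,0.800
Pseudomyrmex brunneus,PseBru,NO,F,0.768
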