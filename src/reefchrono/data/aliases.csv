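raw_name,species_group
Acropora cervicornis,ACER
A. cervicornis,ACER
staghorn coral,ACER
Acropora palmata,APAL
A. palmata,APAL
elkhorn coral,APAL
Agaricia,AGARICIA
Agaricia spp.,AGARICIA
Agaricia agaricites,AGARICIA
Agaricia tenuifolia,AGARICIA
Agaricia lamarcki,AGARICIA
Agaricia fragilis,AGARICIA
Undaria agaricites,AGARICIA
Montastraea cavernosa,MCAV
Montastrea cavernosa,MCAV
M. cavernosa,MCAV
Colpophyllia,COLPOPHYLLIA
Colpophyllia spp.,COLPOPHYLLIA
Colpophyllia natans,COLPOPHYLLIA
Pseudodiploria,PSEUDODIPLORIA
Pseudodiploria spp.,PSEUDODIPLORIA
Pseudodiploria clivosa,PSEUDODIPLORIA
Pseudodiploria strigosa,PSEUDODIPLORIA
Diploria clivosa,PSEUDODIPLORIA
Diploria strigosa,PSEUDODIPLORIA
Diploria labyrinthiformis,PSEUDODIPLORIA
Diploria,PSEUDODIPLORIA
Diploria spp.,PSEUDODIPLORIA
Madracis,MADRACIS
Madracis spp.,MADRACIS
Madracis mirabilis,MADRACIS
Madracis auretenra,MADRACIS
Madracis decactis,MADRACIS
Meandrina,MEANDRINA
Meandrina spp.,MEANDRINA
Meandrina meandrites,MEANDRINA
Millepora,MILLEPORA
Millepora spp.,MILLEPORA
Millepora alcicornis,MILLEPORA
Millepora complanata,MILLEPORA
fire coral,MILLEPORA
Orbicella,ORBICELLA
Orbicella spp.,ORBICELLA
Orbicella annularis,ORBICELLA
Orbicella faveolata,ORBICELLA
Orbicella franksi,ORBICELLA
Montastraea,ORBICELLA
Montastraea spp.,ORBICELLA
Montastrea spp.,ORBICELLA
Montastraea annularis,ORBICELLA
Montastrea annularis,ORBICELLA
M. annularis,ORBICELLA
Montastraea faveolata,ORBICELLA
Montastraea franksi,ORBICELLA
Porites,PORITES_BRANCHING
Porites spp.,PORITES_BRANCHING
Porites porites,PORITES_BRANCHING
P. porites,PORITES_BRANCHING
Porites furcata,PORITES_BRANCHING
Porites divaricata,PORITES_BRANCHING
branching Porites,PORITES_BRANCHING
branching Porites spp.,PORITES_BRANCHING
Porites astreoides,PASTREOIDES
P. astreoides,PASTREOIDES
Siderastrea,SIDERASTREA
Siderastrea spp.,SIDERASTREA
Siderastrea siderea,SIDERASTREA
Siderastrea radians,SIDERASTREA
Stephanocoenia,STEPHANOCOENIA
Stephanocoenia spp.,STEPHANOCOENIA
Stephanocoenia intersepta,STEPHANOCOENIA
Stephanocoenia michelini,STEPHANOCOENIA
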