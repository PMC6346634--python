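species,vector,covariate,posterior_mean,ci_lo,ci_hi
Albizia gummifera,abiotic,diameter,2.4,0.9,3.8
Albizia gummifera,abiotic,logging,0.2,-3.1,3.7
Albizia gummifera,abiotic,hunting_logging,1.3,-1.1,3.7
Erythrophleum suaveolens,abiotic,diameter,2.3,1.2,3.4
Erythrophleum suaveolens,abiotic,logging,1.4,-0.6,3.4
Erythrophleum suaveolens,abiotic,hunting_logging,0.3,-2.4,3.0
Nesogordonia kabingaensis,abiotic,diameter,2.3,1.4,3.2
Nesogordonia kabingaensis,abiotic,logging,-0.6,-1.7,0.5
Nesogordonia kabingaensis,abiotic,hunting_logging,-0.5,-1.5,0.4
Petersianthus macrocarpus,abiotic,diameter,3.3,2.3,4.3
Petersianthus macrocarpus,abiotic,logging,-1.5,-3.1,0.1
Petersianthus macrocarpus,abiotic,hunting_logging,-1.0,-2.3,0.3
Pteleopsis hylodendron,abiotic,diameter,1.5,0.0,3.0
Pteleopsis hylodendron,abiotic,logging,-1.3,-4.0,1.3
Pteleopsis hylodendron,abiotic,hunting_logging,-2.0,-5.1,1.2
Pterocarpus soyauxii,abiotic,diameter,2.8,1.5,4.1
Pterocarpus soyauxii,abiotic,logging,-1.3,-3.0,0.5
Pterocarpus soyauxii,abiotic,hunting_logging,-1.1,-2.8,0.6
Terminalia superba,abiotic,diameter,3.9,2.8,4.9
Terminalia superba,abiotic,logging,0.0,-1.9,1.8
Terminalia superba,abiotic,hunting_logging,-1.3,-3.0,0.4
Angylocalyx pynaertii,animal,diameter,2.4,1.3,3.5
Angylocalyx pynaertii,animal,logging,-0.2,-1.8,1.4
Angylocalyx pynaertii,animal,hunting_logging,-0.2,-1.8,1.4
Celtis adolfi-friderici,animal,diameter,2.9,2.0,3.8
Celtis adolfi-friderici,animal,logging,0.0,-1.2,1.2
Celtis adolfi-friderici,animal,hunting_logging,-0.3,-1.4,0.7
Celtis mildbraedii,animal,diameter,2.4,2.0,2.9
Celtis mildbraedii,animal,logging,-0.2,-1.0,0.5
Celtis mildbraedii,animal,hunting_logging,-0.8,-1.4,-0.1
Cleistopholis patens,animal,diameter,2.4,0.9,4.0
Cleistopholis patens,animal,logging,-1.1,-3.3,1.2
Cleistopholis patens,animal,hunting_logging,-2.0,-4.1,0.1
Diospyros bipindensis,animal,diameter,0.8,-1.4,2.9
Diospyros bipindensis,animal,logging,-1.8,-3.5,0.0
Diospyros bipindensis,animal,hunting_logging,-1.8,-3.7,0.1
Diospyros canaliculata,animal,diameter,0.3,-1.6,2.3
Diospyros canaliculata,animal,logging,0.1,-1.5,1.8
Diospyros canaliculata,animal,hunting_logging,-1.0,-2.4,0.4
Greenwayodendron suaveolens,animal,diameter,4.2,3.4,5.0
Greenwayodendron suaveolens,animal,logging,-0.1,-0.9,0.7
Greenwayodendron suaveolens,animal,hunting_logging,-0.3,-1.0,0.4
Guarea cedrata,animal,diameter,1.8,0.2,3.3
Guarea cedrata,animal,logging,-0.7,-3.0,1.5
Guarea cedrata,animal,hunting_logging,-0.1,-3.3,3.3
Guarea thompsonii,animal,diameter,2.3,1.3,3.4
Guarea thompsonii,animal,logging,-1.1,-2.2,0.1
Guarea thompsonii,animal,hunting_logging,-1.0,-2.1,0.1
Lannea welwitschii,animal,diameter,2.1,0.3,3.8
Lannea welwitschii,animal,logging,-0.2,-4.5,4.0
Lannea welwitschii,animal,hunting_logging,0.6,-4.4,5.2
Macaranga barteri,animal,diameter,2.4,1.1,3.7
Macaranga barteri,animal,logging,-1.0,-2.6,0.6
Macaranga barteri,animal,hunting_logging,-0.8,-2.4,0.8
Staudtia kamerunensis,animal,diameter,1.6,-0.2,3.4
Staudtia kamerunensis,animal,logging,-0.3,-4.1,3.6
Staudtia kamerunensis,animal,hunting_logging,0.0,-6.2,6.2
Strombosia nigropunctata,animal,diameter,1.6,0.6,2.6
Strombosia nigropunctata,animal,logging,-0.5,-1.5,0.5
Strombosia nigropunctata,animal,hunting_logging,-0.6,-1.5,0.4
Strombosia pustulata,animal,diameter,2.2,1.4,3.0
Strombosia pustulata,animal,logging,-0.6,-1.5,0.2
Strombosia pustulata,animal,hunting_logging,-0.3,-1.2,0.6
Strombosiopsis tetrandra,animal,diameter,3.2,2.2,4.1
Strombosiopsis tetrandra,animal,logging,-0.9,-2.1,0.3
Strombosiopsis tetrandra,animal,hunting_logging,-0.6,-1.7,0.6
Xylopia chrysophylla,animal,diameter,1.3,-0.4,3.0
Xylopia chrysophylla,animal,logging,0.1,-3.0,3.2
Xylopia chrysophylla,animal,hunting_logging,-2.5,-5.1,0.2
Xylopia hypolampra,animal,diameter,1.8,0.2,3.4
Xylopia hypolampra,animal,logging,1.6,-2.0,5.1
Xylopia hypolampra,animal,hunting_logging,0.9,-2.4,4.2
Xylopia phloiodora,animal,diameter,1.7,0.0,3.3
Xylopia phloiodora,animal,logging,0.8,-1.4,2.9
Xylopia phloiodora,animal,hunting_logging,1.6,-0.9,4.0
Camptostylus mannii,both,diameter,0.9,-1.1,2.8
Camptostylus mannii,both,logging,0.7,-1.3,2.7
Camptostylus mannii,both,hunting_logging,0.3,-1.6,2.1
Grossera macrantha,both,diameter,2.3,0.9,3.7
Grossera macrantha,both,logging,-1.5,-3.0,-0.1
Grossera macrantha,both,hunting_logging,-0.7,-2.2,0.8
Lepidobotrys staudtii,both,diameter,1.7,-0.1,3.6
Lepidobotrys staudtii,both,logging,-0.2,-3.0,2.6
Lepidobotrys staudtii,both,hunting_logging,0.1,-2.2,2.4
Myrianthus arboreus,both,diameter,1.7,0.6,2.7
Myrianthus arboreus,both,logging,2.1,-0.3,4.5
Myrianthus arboreus,both,hunting_logging,2.3,0.7,3.8
Pausinystalia macroceras,both,diameter,1.1,0.1,2.1
Pausinystalia macroceras,both,logging,-0.1,-1.5,1.3
Pausinystalia macroceras,both,hunting_logging,0.3,-1.0,1.6
Radlkofera calodendron,both,diameter,2.1,0.0,4.2
Radlkofera calodendron,both,logging,-1.9,-4.3,0.7
Radlkofera calodendron,both,hunting_logging,1.5,-2.4,5.4
Rinorea oblongifolia,both,diameter,1.6,-0.5,3.8
Rinorea oblongifolia,both,logging,1.7,-1.7,5.0
Rinorea oblongifolia,both,hunting_logging,-1.9,-5.2,1.1
Thomandersia hensii,both,diameter,2.9,0.0,5.9
Thomandersia hensii,both,logging,1.1,-4.8,6.9
Thomandersia hensii,both,hunting_logging,0.0,-6.2,6.2
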