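species,vector,regime,mean_m,ci_lo_m,ci_hi_m
Albizia gummifera,abiotic,logged,51.3,47.7,54.9
Albizia gummifera,abiotic,protected,52.6,49.4,55.8
Albizia gummifera,abiotic,hunted_logged,53.3,50.3,56.3
Erythrophleum suaveolens,abiotic,logged,42.6,40.2,45.0
Erythrophleum suaveolens,abiotic,protected,31.8,30.0,33.7
Erythrophleum suaveolens,abiotic,hunted_logged,23.4,22.1,24.7
Nesogordonia kabingaensis,abiotic,logged,12.4,9.5,16.5
Nesogordonia kabingaensis,abiotic,protected,41.1,38.1,44.1
Nesogordonia kabingaensis,abiotic,hunted_logged,37.0,33.5,40.6
Petersianthus macrocarpus,abiotic,logged,65.9,64.1,67.7
Petersianthus macrocarpus,abiotic,protected,63.3,61.2,65.6
Petersianthus macrocarpus,abiotic,hunted_logged,61.1,58.6,63.4
Pteleopsis hylodendron,abiotic,logged,43.9,39.0,48.6
Pteleopsis hylodendron,abiotic,protected,36.5,28.4,43.6
Pteleopsis hylodendron,abiotic,hunted_logged,57.5,54.0,61.2
Pterocarpus soyauxii,abiotic,logged,56.9,53.3,60.4
Pterocarpus soyauxii,abiotic,protected,62.9,60.3,65.5
Pterocarpus soyauxii,abiotic,hunted_logged,66.9,64.6,69.2
Terminalia superba,abiotic,logged,68.0,66.6,69.6
Terminalia superba,abiotic,protected,75.0,73.4,76.8
Terminalia superba,abiotic,hunted_logged,75.9,74.3,77.7
Angylocalyx pynaertii,animal,logged,45.0,41.5,48.5
Angylocalyx pynaertii,animal,protected,41.0,37.2,45.0
Angylocalyx pynaertii,animal,hunted_logged,49.9,46.9,52.7
Celtis adolfi-friderici,animal,logged,18.0,16.0,20.3
Celtis adolfi-friderici,animal,protected,14.5,13.2,15.9
Celtis adolfi-friderici,animal,hunted_logged,13.8,12.9,14.8
Celtis mildbraedii,animal,logged,20.1,18.7,21.6
Celtis mildbraedii,animal,protected,10.3,9.9,10.8
Celtis mildbraedii,animal,hunted_logged,21.0,19.8,22.3
Cleistopholis patens,animal,logged,17.8,13.8,21.7
Cleistopholis patens,animal,protected,38.4,30.1,43.6
Cleistopholis patens,animal,hunted_logged,38.4,34.4,42.3
Diospyros bipindensis,animal,logged,41.9,38.7,45.2
Diospyros bipindensis,animal,protected,39.8,36.7,43.1
Diospyros bipindensis,animal,hunted_logged,39.5,35.2,43.8
Diospyros canaliculata,animal,logged,45.9,42.8,49.0
Diospyros canaliculata,animal,protected,36.8,33.2,40.2
Diospyros canaliculata,animal,hunted_logged,13.9,12.8,15.0
Greenwayodendron suaveolens,animal,logged,37.2,35.7,38.7
Greenwayodendron suaveolens,animal,protected,31.4,30.2,32.7
Greenwayodendron suaveolens,animal,hunted_logged,42.4,40.5,44.2
Guarea cedrata,animal,logged,35.3,31.0,39.7
Guarea cedrata,animal,protected,28.0,19.5,35.1
Guarea cedrata,animal,hunted_logged,39.2,35.9,42.6
Guarea thompsonii,animal,logged,40.7,37.5,44.0
Guarea thompsonii,animal,protected,40.2,36.4,43.9
Guarea thompsonii,animal,hunted_logged,46.9,43.7,50.1
Lannea welwitschii,animal,logged,42.5,37.3,47.6
Lannea welwitschii,animal,protected,2.2,1.0,8.7
Lannea welwitschii,animal,hunted_logged,16.9,14.0,20.6
Macaranga barteri,animal,logged,10.2,8.4,12.5
Macaranga barteri,animal,protected,24.4,20.6,28.3
Macaranga barteri,animal,hunted_logged,4.5,3.6,6.0
Staudtia kamerunensis,animal,logged,49.9,45.2,55.2
Staudtia kamerunensis,animal,protected,34.2,22.9,42.0
Staudtia kamerunensis,animal,hunted_logged,49.0,45.7,52.5
Strombosia nigropunctata,animal,logged,21.1,19.5,22.8
Strombosia nigropunctata,animal,protected,9.8,9.1,10.5
Strombosia nigropunctata,animal,hunted_logged,19.6,18.3,21.0
Strombosia pustulata,animal,logged,17.5,15.9,19.2
Strombosia pustulata,animal,protected,15.6,14.5,16.9
Strombosia pustulata,animal,hunted_logged,14.2,12.7,15.9
Strombosiopsis tetrandra,animal,logged,19.2,18.1,20.3
Strombosiopsis tetrandra,animal,protected,28.7,26.7,30.7
Strombosiopsis tetrandra,animal,hunted_logged,41.4,38.9,43.9
Xylopia chrysophylla,animal,logged,40.4,36.9,44.0
Xylopia chrysophylla,animal,protected,34.4,27.9,40.0
Xylopia chrysophylla,animal,hunted_logged,42.9,40.3,45.6
Xylopia hypolampra,animal,logged,98.5,95.3,100.0
Xylopia hypolampra,animal,protected,98.8,96.1,100.0
Xylopia hypolampra,animal,hunted_logged,98.0,93.6,99.9
Xylopia phloiodora,animal,logged,47.8,44.3,51.2
Xylopia phloiodora,animal,protected,45.7,42.2,49.2
Xylopia phloiodora,animal,hunted_logged,44.7,41.3,48.1
Camptostylus mannii,both,logged,42.3,38.9,45.6
Camptostylus mannii,both,protected,41.5,38.0,45.1
Camptostylus mannii,both,hunted_logged,39.7,36.5,43.0
Grossera macrantha,both,logged,40.5,35.6,45.0
Grossera macrantha,both,protected,51.9,49.2,54.5
Grossera macrantha,both,hunted_logged,43.9,40.1,46.9
Lepidobotrys staudtii,both,logged,35.9,27.9,42.1
Lepidobotrys staudtii,both,protected,45.7,41.9,49.4
Lepidobotrys staudtii,both,hunted_logged,51.1,47.9,54.3
Myrianthus arboreus,both,logged,34.2,28.8,39.0
Myrianthus arboreus,both,protected,43.3,39.8,46.6
Myrianthus arboreus,both,hunted_logged,25.3,22.7,28.1
Pausinystalia macroceras,both,logged,37.1,34.0,40.3
Pausinystalia macroceras,both,protected,31.2,28.8,33.7
Pausinystalia macroceras,both,hunted_logged,39.0,35.6,42.4
Radlkofera calodendron,both,logged,41.3,37.4,45.1
Radlkofera calodendron,both,protected,45.7,42.1,49.0
Radlkofera calodendron,both,hunted_logged,42.4,38.9,46.0
Rinorea oblongifolia,both,logged,46.7,43.6,49.8
Rinorea oblongifolia,both,protected,31.7,27.0,36.3
Rinorea oblongifolia,both,hunted_logged,46.7,43.3,50.0
Thomandersia hensii,both,logged,38.0,31.9,43.2
Thomandersia hensii,both,protected,54.0,50.9,57.2
Thomandersia hensii,both,hunted_logged,37.9,31.5,43.1
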