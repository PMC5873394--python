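(((Sericytochromatia_1:3000,((Melainabacteria_1:2000,Melainabacteria_2:2000):800,(Cyanobacteria_Gloeobacter:2400,(Cyanobacteria_1:2000,Cyanobacteria_2:2000):400):400):200):500,(Chloroflexi_1:3200,(Chloroflexi_2:2600,(GNS_1:1900,GNS_2:1900):700):600):300):400,(Alphaproteobacteria_1:3600,(Bacteroidetes_1:3300,(Ignavibacteria_1:3000,(GSB_1:1750,GSB_2:1750):1250):300):300):300);
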