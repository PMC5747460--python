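population,region,122-121,121-122,121-120,120-119,122-120
Cyprus,invaded,100.00,0,0,0,0
Lisbon,invaded,100.00,0,0,0,0
Piombino (IT),invaded,100.00,0,0,0,0
Giglio C. (IT),invaded,90.00,10.00,0,0,0
Giglio A. (IT),invaded,100.00,0,0,0,0
Calabria1 (IT),invaded,100.00,0,0,0,0
Genova O. B. (IT),invaded,63.63,36.36,0,0,0
Sestri (IT),invaded,70.00,30.00,0,0,0
Imperia (IT),invaded,76.92,7.69,7.69,0,7.69
Ittiri (IT),invaded,100.00,0,0,0,0
Palermo O. B. (IT),invaded,90.00,10.00,0,0,0
Ficarra (IT),invaded,100.00,0,0,0,0
Capoliveri (IT),invaded,75.00,8.33,8.33,8.33,0
Capraia (IT),invaded,100.00,0,0,0,0
Cavo (IT),invaded,80.00,10.00,10.00,0,0
Enfola (IT),invaded,100.00,0,0,0,0
M. Campo-Lac. (IT),invaded,100.00,0,0,0,0
Malta2,invaded,66.66,16.66,0,16.66,0
S. Andrea (IT),invaded,80.00,0,20.00,0,0
Kirstenbosch (SA),native,100.00,0,0,0,0
Tanqua Karoo (SA),native,66.66,0,0,0,33.33
Jacobsbaii (SA),native,100.00,0,0,0,0
Calabria2 (IT),invaded,100.00,0,0,0,0
Castiglioncello (IT),invaded,70.00,20.00,10.00,0,0
Chiessi (IT),invaded,66.66,6.66,6.66,13.33,6.66
Rodi Garganico (IT),invaded,80.00,6.66,6.66,6.66,0
Stintino (IT),invaded,86.66,0,6.66,6.66,0
Giannutri (IT),invaded,100.00,0,0,0,0
Hanbury (IT),invaded,40.00,40.00,0,0,20.00
Malta3,invaded,93.33,0,0,6.66,0
Malta1,invaded,62.50,37.50,0,0,0
Marocco,invaded,90.00,0,0,0,10.00
Pianosa (IT),invaded,92.30,0,0,7.69,0
Pollina (IT),invaded,100.00,0,0,0,0
Rio Marina (IT),invaded,73.33,13.33,13.33,0,0
Riomaggiore (IT),invaded,100.00,0,0,0,0
Ventotene (IT),invaded,100.00,0,0,0,0
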