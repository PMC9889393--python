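site_id,year,name,country,latitude,longitude,site_type,coverage
FI-Hyy,2015,Hyytiala,Finland,61.84741,24.29477,Evergreen needleleaf forests,0.53
FI-Ken,2020,Kenttarova,Finland,67.98721,24.24301,Evergreen needleleaf forests,0.30
FI-Let,2012,Lettosuo,Finland,60.64183,23.95952,Evergreen needleleaf forests,0.50
FI-Sii,2020,Siikaneva,Finland,61.83265,24.19285,Permanent wetlands,0.55
FI-Var,2018,Varrio,Finland,67.7549,29.61,Evergreen needleleaf forests,0.46
FI-Qvd,2020,Qvidja,Finland,60.29550,22.39281,Agricultural grassland,0.40
SE-Deg,2006,Degero,Sweden,64.18203,19.55654,Permanent wetlands,0.63
SE-Nor,2020,Norunda,Sweden,60.0865,17.479504,Evergreen needleleaf forests,0.53
SE-Svb,2020,Svartberget,Sweden,64.25611,19.7745,Evergreen needleleaf forests,0.40
SE-Ros,2018,Rosinedal-3,Sweden,64.1725,19.738,Evergreen needleleaf forests,0.39
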