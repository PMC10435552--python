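nest_id,taxon,proportion_pct
A1,Brassica napus,54.21
A2,Brassica napus,28.25
A3,Brassica napus,6.17
A4,Brassica napus,50.72
A5,Brassica napus,52.15
A6,Brassica napus,6.00
A7,Brassica napus,51.18
A8,Brassica napus,45.35
A9,Brassica napus,43.61
A10,Brassica napus,45.21
A11,Brassica napus,8.50
A12,Brassica napus,10.14
A1,Acer sp.,30.74
A3,Acer sp.,28.30
A4,Acer sp.,18.56
A5,Acer sp.,17.38
A7,Acer sp.,42.31
A8,Acer sp.,4.74
A10,Acer sp.,4.71
A11,Acer sp.,0.59
A1,Achillea typ,0.17
A1,Aesculus sp.,0.17
A2,Aesculus sp.,0.41
A5,Aesculus sp.,0.19
A7,Aesculus sp.,0.54
A11,Aesculus sp.,0.79
A9,Caprifoliaceae/Lonicera,0.39
A8,Carex sp.,0.38
A10,Carex sp.,7.90
A12,Carex sp.,3.11
A2,Caryophyllaceae,0.41
A3,Caryophyllaceae,0.17
A4,Caryophyllaceae,0.41
A8,Centaurea cyanus,0.19
A3,Chenopodiaceae,0.17
A8,Cornus sp.,0.38
A10,Eleagnus sp.,0.34
A1,Hypericum sp.,5.29
A2,Hypericum sp.,0.62
A3,Hypericum sp.,1.03
A4,Hypericum sp.,0.41
A5,Hypericum sp.,0.56
A6,Hypericum sp.,7.35
A9,Hypericum sp.,0.98
A11,Hypericum sp.,9.68
A12,Hypericum sp.,21.33
A1,Juglans sp.,0.50
A2,Juglans sp.,1.24
A4,Juglans sp.,0.62
A5,Juglans sp.,0.56
A6,Juglans sp.,0.39
A7,Juglans sp.,0.18
A8,Juglans sp.,1.14
A12,Juglans sp.,0.62
A8,Lamium sp.,0.19
A11,Lamium sp.,0.40
A9,Malus sp.,0.79
A10,Malus sp.,0.50
A2,Papaver sp.,0.82
A3,Papaver sp.,0.17
A6,Papaver sp.,0.58
A8,Papaver sp.,0.38
A9,Papaver sp.,0.20
A3,Pinus sp.,0.17
A4,Pinus sp.,0.21
A5,Pinus sp.,0.19
A8,Pinus sp.,0.19
A10,Pinus sp.,0.17
A11,Pinus sp.,0.40
A1,Plantago sp.,0.50
A2,Plantago sp.,1.24
A6,Plantago sp.,0.39
A10,Plantago sp.,0.34
A11,Plantago sp.,0.59
A12,Plantago sp.,1.45
A1,Poaceae,1.16
A2,Poaceae,8.87
A3,Poaceae,1.20
A4,Poaceae,3.71
A5,Poaceae,5.79
A6,Poaceae,25.73
A8,Poaceae,17.46
A9,Poaceae,2.36
A10,Poaceae,5.21
A11,Poaceae,59.88
A12,Poaceae,27.74
A1,Prunus sp.,0.83
A2,Prunus sp.,2.27
A4,Prunus sp.,0.21
A5,Prunus sp.,0.75
A6,Prunus sp.,1.55
A8,Prunus sp.,2.28
A9,Prunus sp.,0.59
A10,Prunus sp.,2.69
A11,Prunus sp.,3.36
A12,Prunus sp.,3.73
A2,Pyrus sp.,9.90
A1,Quercus sp.,3.64
A2,Quercus sp.,5.15
A3,Quercus sp.,10.81
A4,Quercus sp.,3.30
A5,Quercus sp.,19.44
A6,Quercus sp.,1.55
A7,Quercus sp.,5.24
A8,Quercus sp.,6.83
A9,Quercus sp.,14.93
A10,Quercus sp.,4.87
A11,Quercus sp.,5.53
A12,Quercus sp.,1.24
A1,Ranunculus sp.,1.16
A2,Ranunculus sp.,38.97
A3,Ranunculus sp.,0.51
A4,Ranunculus sp.,21.24
A5,Ranunculus sp.,1.31
A6,Ranunculus sp.,42.75
A7,Ranunculus sp.,0.54
A8,Ranunculus sp.,0.38
A9,Ranunculus sp.,9.82
A10,Ranunculus sp.,5.04
A11,Ranunculus sp.,4.35
A12,Ranunculus sp.,27.95
A2,Rubus sp.,1.86
A3,Rubus sp.,11.32
A5,Rubus sp.,1.12
A6,Rubus sp.,13.15
A8,Rubus sp.,19.54
A9,Rubus sp.,5.50
A10,Rubus sp.,21.51
A11,Rubus sp.,5.93
A12,Rubus sp.,1.66
A1,Rumex sp.,0.17
A3,Rumex sp.,38.94
A9,Rumex sp.,18.86
A12,Rumex sp.,0.21
A1,Salix sp.,1.49
A3,Salix sp.,0.17
A5,Salix sp.,0.19
A9,Salix sp.,0.39
A10,Salix sp.,0.17
A12,Salix sp.,0.62
A3,Trifolium repens,0.86
A4,Trifolium repens,0.62
A5,Trifolium repens,0.37
A6,Trifolium repens,0.58
A8,Trifolium repens,0.57
A9,Trifolium repens,1.57
A10,Trifolium repens,0.67
A12,Trifolium repens,0.21
A10,Viola tricolor,0.67
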