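# 20 diffusion gradient directions (unit vectors, x y z) from antipodally-symmetric electrostatic repulsion
0.0024072647 -0.1074748614 0.9942048880
-0.2372366041 0.3624671405 0.9012970463
0.4087470547 0.3071780214 0.8593995046
0.4537751638 -0.3399788158 0.8237126353
-0.5403830005 -0.1874217271 0.8202800186
-0.1082053555 -0.6265463846 0.7718362709
0.2163875898 0.7428616470 0.6335084722
0.8125952586 0.1368673119 0.5665300385
-0.7660975410 0.3233233254 0.5554786989
-0.3741547151 0.7449352190 0.5523402654
0.3654875549 -0.8263882564 0.4283705135
0.7926511087 -0.4408024039 0.4211857792
-0.6268228520 -0.6622859645 0.4104514752
-0.9040909816 -0.2053716317 0.3747559072
-0.1827636651 -0.9381728737 0.2939882681
0.5009266310 0.8418530431 0.2008879393
0.8695555763 0.4672719997 0.1597810319
-0.1302660443 0.9817551257 0.1385194242
-0.6992765966 0.7105193115 0.0785783012
0.9879034550 -0.1545326190 0.0129009028
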