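pdb_id,name,v_m,resolution
2BO4,Mannosylglycerate synthase,5.50,1.95
3DER,Dipeptide epimerase,4.77,1.90
2W5F,Endo-1-4-beta-D-xylanase,4.74,1.90
2W5E,Astrovirus serine protease,4.71,2.00
1KOR,Argininosuccinate synthetase,4.53,1.95
1TG7,Beta-galactosidase,4.50,1.90
3IA2,Arylesterase,4.46,1.65
2ZXQ,Endo-alpha-N-acetylgalactosaminidase,4.38,2.00
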