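ligand,compound_type,pfs,mep_pct,mep_fc,vmax_pct_per_min,vmax_fc,abn_per_cell,displacement,ec50_p_um,ec50_d24_um,ec50_d48_um
TAX,control,-10.8,100.0,5.0,5.8,5.9,0.96,yes,0.02,,
RAL,RAL-like,-3.4,34.5,1.7,2.8,2.9,0.91,yes,26.8,75.9,54.2
LAS,RAL-like,-3.0,23.5,1.2,1.5,1.5,0.87,no,20.8,48.1,26.7
5C6,TAM-like,-3.9,26.7,1.3,1.7,1.7,0.69,yes,,23.4,
5C7,TAM-like,-3.6,22.3,1.1,1.3,1.3,0.53,no,,26.7,27.4
5JY,TAM-like,-3.6,18.7,0.9,1.0,1.1,0.57,no,24.4,52.8,44.6
TAM,TAM-like,-3.7,10.2,0.5,0.4,0.4,0.46,no,61.3,76.4,75.1
OB7,OBHSN,-4.3,26.0,1.3,1.5,1.5,0.41,no,121.4,,
OB3,OBHSN,-3.5,21.9,1.1,1.3,1.3,0.33,no,133.4,,
EST,OBHSN,-2.9,12.7,0.6,0.6,0.6,0.47,no,39.2,78.3,77.4
DMSO,vehicle,,20.5,1.0,1.0,1.0,0.22,no,,,
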