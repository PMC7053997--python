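table,construct,ligand,assay,pK,K_nM,n
radioligand,WT,spiperone,saturation,9.74,0.18,3
radioligand,WT-Na,spiperone,saturation,9.70,0.20,3
radioligand,I122A,spiperone,saturation,9.74,0.18,3
radioligand,I122W,spiperone,saturation,8.95,1.15,3
radioligand,WT,risperidone,competition,8.55,2.8,8
radioligand,WT-Na,risperidone,competition,8.96,1.1,6
radioligand,I122A,risperidone,competition,8.14,7.9,8
radioligand,I122W,risperidone,competition,7.43,37,5
radioligand,WT,eticlopride,competition,9.84,0.14,3
radioligand,I122A,eticlopride,competition,10.33,0.04,3
radioligand,I122W,eticlopride,competition,9.61,0.25,4
trfret,WT,spiperone-d2,saturation,8.54,2.88,9
trfret,L94A,spiperone-d2,saturation,7.71,19.5,5
trfret,W100A,spiperone-d2,saturation,7.39,40.7,9
trfret,I184A,spiperone-d2,saturation,8.79,1.62,5
trfret,WT,eticlopride,competition,10.06,0.09,8
trfret,L94A,eticlopride,competition,9.08,0.83,4
trfret,W100A,eticlopride,competition,8.06,8.71,4
trfret,I184A,eticlopride,competition,9.34,0.45,4
trfret,WT,risperidone,competition,8.47,3.34,7
trfret,L94A,risperidone,competition,8.02,9.54,5
trfret,W100A,risperidone,competition,7.60,25.1,7
trfret,I184A,risperidone,competition,9.33,0.47,5
trfret,WT,spiperone,competition,9.96,0.11,8
trfret,L94A,spiperone,competition,8.36,4.37,5
trfret,W100A,spiperone,competition,8.39,4.07,7
trfret,I184A,spiperone,competition,9.78,0.17,5
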