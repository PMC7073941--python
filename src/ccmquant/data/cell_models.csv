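organism_id,cell_dw_g,cell_volume_L,specific_volume_L_per_g,note
B_subtilis,2.2e-13,9e-16,4.09e-3,literature single-cell dry weight and volume
S_cerevisiae,1.65e-11,4.4e-14,2.66e-3,printed specific volume disagrees with exact division in the third digit
N_oceanica,1.19e-11,1.4e-14,1.18e-3,cell volume and dry weight from separate literature sources
P_tricornutum,4.88e-11,1.22e-13,2.51e-3,half-parallelepiped geometric volume (20 x 3.5 x 3.5 um / 2)
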