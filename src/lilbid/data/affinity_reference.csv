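sample,scaffold,pct_gc,theor_tm_c,uv_tm_c,uv_tm_sem_c,n_uv,itc_kd_nm,itc_kd_sem_nm,n_itc,pct_ss_1p1mm,pct_ss_sem,n_lilbid,role
9_Amer,35_Amer,22.2,22.4,22.7,0.9,2,8500,700,3,77,3,5,model
10_Amer,35_Amer,20.0,26.7,26.0,1.4,2,3900,500,3,79,2,5,test
11_Amer,35_Amer,27.3,34.3,34.6,1.2,2,370,50,5,65,5,5,test
15_Amer,35_Amer,13.3,41.6,40.0,1.4,4,31.2,0.8,3,47,4,5,test
15b_Amer,35_Amer,26.7,47.1,47.5,0.4,4,3.6,0.5,3,36,3,5,model
20_Amer,35_Amer,25.0,56.2,55.8,1.3,2,,,,8,3,5,model
9_Bmer,35_Bmer,44.4,31.4,33.3,0.1,2,2120,60,3,68.5,0.9,5,model
10_Bmer,35_Bmer,40.0,35.1,35.3,1.8,2,353,7,3,70.6,3,5,model
12_Bmer,35_Bmer,50.0,45.2,49.1,1.3,2,20.1,1.8,3,34.6,1.4,5,model
8_Cmer,35_Cmer,62.5,30.7,34,2,4,418,16,4,61.7,1.2,5,model
10_Cmer,35_Cmer,60.0,44.4,44,2,3,29,7,3,46,3,5,model
12_Cmer,35_Cmer,58.3,51.4,52.6,0.2,2,,,,40.4,1.9,5,model
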