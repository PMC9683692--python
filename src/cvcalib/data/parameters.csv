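name,units,value,min,max,status
q_sbv,m3,0.001041,0.0005,0.002,free
E_LVa,MPa/m3,341.0,100.0,1000.0,free
E_RVa,MPa/m3,73.3,20.0,250.0,free
R_par,MPa.s/m3,10.7,2.0,50.0,free
R_LE_T,MPa.s/m3,2078.0,500.0,8000.0,free
R_BR_T,MPa.s/m3,7178.0,1800.0,28000.0,free
R_AC_T,MPa.s/m3,6954.0,1700.0,28000.0,free
R_EC_T,MPa.s/m3,4164.0,1000.0,17000.0,free
R_MC_T,MPa.s/m3,4452.0,1100.0,18000.0,free
R_PC_T,MPa.s/m3,19192.0,4800.0,77000.0,free
R_TR_T,MPa.s/m3,880.0,220.0,3600.0,free
C_V,m3/MPa,0.5,0.1,2.0,free
T,s,1.0,0.3,2.0,fixed
t_sys,s,0.3,0.1,0.5,fixed
t_atr,s,0.15,0.05,0.3,fixed
atr_onset,s,0.8,0.0,2.0,fixed
E_RAb,MPa/m3,20.0,1.0,50.0,fixed
E_RAa,MPa/m3,45.0,5.0,100.0,fixed
E_RVb,MPa/m3,12.0,1.0,50.0,fixed
E_LAb,MPa/m3,30.0,1.0,50.0,fixed
E_LAa,MPa/m3,60.0,5.0,150.0,fixed
E_LVb,MPa/m3,20.0,2.0,100.0,fixed
R_trv,MPa.s/m3,0.8,0.1,10.0,fixed
R_puv,MPa.s/m3,0.8,0.1,10.0,fixed
R_miv,MPa.s/m3,0.8,0.1,10.0,fixed
R_aov,MPa.s/m3,0.6,0.1,10.0,fixed
p_smooth,MPa,1e-05,1e-06,0.0001,fixed
C_par,m3/MPa,0.004,0.0005,0.02,fixed
C_pvn,m3/MPa,0.17,0.01,0.2,fixed
R_pvn,MPa.s/m3,1.5,0.2,10.0,fixed
C_aor,m3/MPa,0.0025,0.0005,0.01,fixed
C_ubr,m3/MPa,0.0012,0.0002,0.005,fixed
C_cer,m3/MPa,0.0005,0.0001,0.002,fixed
C_mca,m3/MPa,0.0001,2e-05,0.0005,fixed
C_bra,m3/MPa,0.0002,4e-05,0.001,fixed
C_dao,m3/MPa,0.0015,0.0003,0.006,fixed
R_aor_ubr,MPa.s/m3,4.0,0.5,20.0,fixed
R_aor_dao,MPa.s/m3,2.5,0.5,20.0,fixed
R_ubr_cer,MPa.s/m3,8.0,1.0,40.0,fixed
R_ubr_bra,MPa.s/m3,10.0,1.0,50.0,fixed
R_cer_mca,MPa.s/m3,15.0,2.0,60.0,fixed
C_LE_T,m3/MPa,0.001,0.0002,0.005,fixed
C_BR_T,m3/MPa,0.001,0.0002,0.005,fixed
C_AC_T,m3/MPa,0.001,0.0002,0.005,fixed
C_EC_T,m3/MPa,0.001,0.0002,0.005,fixed
C_MC_T,m3/MPa,0.001,0.0002,0.005,fixed
C_PC_T,m3/MPa,0.001,0.0002,0.005,fixed
C_TR_T,m3/MPa,0.001,0.0002,0.005,fixed
R_LE_ven,MPa.s/m3,208.0,20.0,2000.0,fixed
R_BR_ven,MPa.s/m3,718.0,70.0,7000.0,fixed
R_AC_ven,MPa.s/m3,695.0,70.0,7000.0,fixed
R_EC_ven,MPa.s/m3,416.0,40.0,4000.0,fixed
R_MC_ven,MPa.s/m3,445.0,40.0,4000.0,fixed
R_PC_ven,MPa.s/m3,1919.0,190.0,19000.0,fixed
R_TR_ven,MPa.s/m3,88.0,9.0,900.0,fixed
f_vub,1,0.45,0.1,0.9,fixed
R_svc,MPa.s/m3,1.0,0.1,10.0,fixed
R_ivc,MPa.s/m3,0.8,0.1,10.0,fixed
q0_ra,m3,2e-05,0.0,0.0002,fixed
q0_rv,m3,4e-05,0.0,0.0002,fixed
q0_la,m3,2e-05,0.0,0.0002,fixed
q0_lv,m3,3e-05,0.0,0.0002,fixed
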