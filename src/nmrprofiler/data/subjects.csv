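sample_id,group,age,sex,tanner,height_cm,weight_kg,bmi,bmi_sds
t1dm_1,T1DM,17.2,M,5,167.0,54.0,19.4,-0.38
t1dm_2,T1DM,15.0,F,5,159.0,58.0,22.9,1.01
t1dm_3,T1DM,11.4,M,2,152.0,37.0,16.0,-0.52
t1dm_4,T1DM,10.0,F,1,148.0,34.5,15.8,-0.31
t1dm_5,T1DM,8.7,F,1,140.0,33.2,16.9,0.59
t1dm_6,T1DM,11.8,M,2,149.0,40.5,18.2,0.37
t1dm_7,T1DM,10.1,M,1,139.5,30.0,15.4,-0.53
control_1,control,15.0,M,5,172.8,58.9,19.7,0.23
control_2,control,9.9,M,1,139.0,30.3,15.7,-0.38
control_3,control,11.6,M,1,147.0,42.2,19.5,0.92
control_4,control,12.6,F,2,158.7,40.9,16.2,-0.81
control_5,control,12.5,F,3,151.9,41.0,17.8,-0.11
control_6,control,17.8,F,5,168.4,60.1,21.2,0.14
control_7,control,15.2,M,4,179.1,64.1,20.0,0.32
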