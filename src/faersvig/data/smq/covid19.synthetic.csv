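smq_name,scope,pt
COVID-19,narrow,COVID-19
COVID-19,narrow,COVID-19 pneumonia
COVID-19,narrow,Asymptomatic COVID-19
COVID-19,narrow,Suspected COVID-19
COVID-19,narrow,Coronavirus infection
COVID-19,narrow,Coronavirus test positive
COVID-19,narrow,SARS-CoV-2 test positive
COVID-19,narrow,SARS-CoV-2 antibody test positive
COVID-19,narrow,SARS-CoV-2 RNA increased
COVID-19,narrow,SARS-CoV-2 sepsis
COVID-19,narrow,SARS-CoV-2 viraemia
COVID-19,narrow,Severe acute respiratory syndrome
COVID-19,narrow,Multisystem inflammatory syndrome in children
COVID-19,narrow,Post-acute COVID-19 syndrome
COVID-19,narrow,Exposure to SARS-CoV-2
COVID-19,narrow,Occupational exposure to SARS-CoV-2
COVID-19,narrow,Coronavirus test
COVID-19,narrow,COVID-19 prophylaxis
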