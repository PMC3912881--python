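item,label,recital_median,recital_mean,recital_sd,recital_p,audition_median,audition_mean,audition_sd,audition_p
1,"The simulation (including backstage, the audience, spot-lights, etc.) provided a realistic experience",4.0,3.42,1.08,ns,4.0,3.67,0.50,0.005
2,"The steps involved in the simulation (i.e., waiting backstage, walking on stage, etc.) closely approximated a real performance situation",4.0,3.75,0.75,0.013,3.5,3.50,1.00,ns
3,"I behaved and presented myself in the same way as I do in a real performance",4.0,3.42,1.24,ns,4.0,3.67,0.98,0.046
4,"The interaction with the backstage manager was realistic",4.5,4.00,1.20,0.018,4.0,3.92,1.24,0.029
5,"The CCTV footage in the backstage area was realistic",3.0,2.83,1.40,ns,4.0,3.58,1.56,ns
6,"The sounds heard in the backstage area were realistic",3.5,3.42,1.08,ns,4.0,4.00,1.12,0.028
7,"The decor of the backstage area (including signage and lighting) was realistic",4.0,3.67,0.49,0.005,3.5,3.42,1.08,ns
8,"The transition from backstage on to stage was realistic",4.0,4.08,0.90,0.008,4.0,3.67,0.98,0.046
9,"The interaction with the audience in the performance space was realistic",3.5,3.42,1.08,ns,3.5,3.42,1.08,ns
10,"The spot-lights in the performance space were realistic",4.5,4.08,1.08,0.012,3.5,3.42,1.37,ns
11,"The curtains in the performance space were realistic",3.0,3.33,0.98,ns,3.0,3.17,0.93,ns
12,"The simulation could be used to enhance my musical skills",4.0,4.25,0.86,0.005,4.0,4.25,0.75,0.004
13,"The simulation could be used to enhance my technical skills",5.0,4.33,0.98,0.005,4.5,4.33,0.77,0.004
14,"The simulation could be used to enhance my communicative/presentational skills",3.0,3.58,1.31,ns,4.0,4.17,0.83,0.006
15,"The simulation could be used to help me manage performance anxiety and/or other performance problems",4.0,4.17,0.93,0.007,4.0,4.33,0.77,0.003
16,"The simulation could be used to highlight strengths in my performance",4.5,4.33,0.88,0.004,4.0,4.17,0.71,0.004
17,"The simulation could be used to highlight weaknesses in my performance",4.5,4.25,0.88,0.006,4.5,4.42,0.66,0.003
18,"I would recommend the simulation to people who are interested in developing/refining their performance skills",5.0,4.33,1.10,0.005,4.5,4.42,0.66,0.003
19,"I would recommend the simulation to people who are interested in teaching performance skills",5.0,4.42,1.16,0.004,4.5,4.33,0.77,0.004
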