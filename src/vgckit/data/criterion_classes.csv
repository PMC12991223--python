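criterion,class
Q1,demarcation
Q2,demarcation
Q3,demarcation
Q4,demarcation
Q5,demarcation
Q6,disturbance
Q7,disturbance
Q8,disturbance
Q9,disturbance
Q10,disturbance
Q11,bone
Q12,bone
Q13,tumor
Q14,tumor
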