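game_id,framing,p_risky,risky_payoff,sure_payoff
g1,positive,0.1,250,50
g2,positive,0.3,500,250
g3,positive,0.5,1000,500
g4,positive,0.7,500,250
g5,positive,0.9,2000,1500
g1,negative,0.1,1200,400
g2,negative,0.3,1800,600
g3,negative,0.5,1000,500
g4,negative,0.7,600,200
g5,negative,0.9,2400,1200
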