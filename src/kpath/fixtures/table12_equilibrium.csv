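sample,V_wsk_nek,V_ek_nek,Z_nek,direction_nek,V_wsk_ek,V_nek_ek,Z_ek,direction_ek
RSWKH,-0.89,-1.16,-1.06,"β,χ",-0.78,-1.39,-1.14,"θ,ω"
RSWKL,-0.78,-1.04,-1.2,"α,χ",-0.78,-1.51,-1.02,"θ,λ"
RSWH,-0.02,-0.44,-0.47,"α,χ",-0.19,-0.5,-0.44,"θ,λ"
RSWL,-0.35,-0.25,-0.27,"α,χ",-0.32,-0.28,-0.24,"θ,λ"
RSKH,-1.25,-1.16,-1.11,"β,χ",-0.8,-1.79,-1.14,"θ,ω"
RSKL,-0.55,-1.11,-1.19,"β,γ",-0.82,-1.19,-1.09,"θ,λ"
ROPTH,-1.93,-0.81,-0.75,"β,χ",-0.65,-2.11,-0.79,"θ,ω"
ROPTL,-0.91,-0.70,-0.84,"β,γ",-0.51,-1.48,-0.69,"θ,λ"
NRSWKH,1.05,0.08,0.36,"β,χ",0.14,1.43,0.08,"ε,λ"
NRSWKL,-0.56,0.11,0.22,"α,χ",-0.45,0.54,0.11,"θ,ω"
NRSWH,3.78,1.69,1.68,"β,χ",3.24,1.28,1.66,"ε,λ"
NRSWL,1.37,1.45,1.58,"α,χ",0.79,2.73,1.42,"θ,λ"
NRSKH,1.24,-0.03,0.26,"β,χ",0.92,0.17,-0.03,"ε,λ"
NRSKL,0.42,0.63,0.73,"β,χ",0.11,1.45,0.61,"θ,ω"
NROPTH,-0.15,1.17,1.02,"β,γ",-0.12,1.76,1.14,"θ,ω"
NROPTL,-0.47,1.56,1.04,"β,γ",0.23,0.90,1.53,"θ,ω"
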