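# RICP 10 s voltage-clamp protocol (reconstructed fixture, v1).
# Constraints honoured from the published method: 10 s total; I_6mV step
# onset at 500 ms (measured at 600 ms); I_Kr sub-segment 750 ms @ +6 mV,
# 7 ms @ -41 mV, then step to +9 mV (measured at 1262 ms).  Remaining
# segments are designed so each labeled time point (1986 I_CaL, 2760 I_Na,
# 3641 I_to, 4300 I_K1, 5840 I_f, 9040 I_Ks) is dominated by its target
# current: -40 mV Na-inactivating pre-pulse before the I_CaL step, -95 mV
# recovery before the I_Na step, +45 mV step for I_to, a long -120 mV step
# for I_K1 and funny-current activation with an I_f tail read at -60 mV,
# and a 2 s +40 mV step for I_Ks.
kind,duration_ms,v_start_mV,v_end_mV
step,500,-80,-80
step,750,6,6
step,7,-41,-41
step,93,9,9
step,430,-80,-80
step,200,-40,-40
step,100,2,2
ramp,50,2,-95
step,628.5,-95,-95
step,31.5,-30,-30
ramp,50,-30,-80
step,760,-80,-80
step,150,45,45
step,450,-80,-80
step,1600,-120,-120
step,100,-60,-60
step,1100,-80,-80
step,2060,40,40
ramp,400,40,-80
step,540,-80,-80
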