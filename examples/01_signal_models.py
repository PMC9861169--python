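"""Closed-form signal physics: Larmor frequencies and relaxation curves.

Prints the proton precession frequency at clinical field strengths and
evaluates the two relaxation models at their characteristic points.
"""

from relaxmap import RelaxationMode, SignalModelParams, larmor_frequency, relaxation_signal
from relaxmap.physics import full_signal

for b0 in (1.5, 3.0):
    print(f"B0 = {b0} T  ->  f0 = {larmor_frequency(b0):.8f} MHz")

# At t = T the recovery model reaches 1 - 1/e of its plateau and the
# decay model falls to 1/e of its initial value.
t1 = SignalModelParams(amplitude=1.0, relax_time=800.0, mode=RelaxationMode.SR_RECOVERY)
t2 = SignalModelParams(amplitude=1.0, relax_time=800.0, mode=RelaxationMode.DECAY)
print(f"recovery at t = T : {relaxation_signal(800.0, t1):.5f}  (63.2% of plateau)")
print(f"decay at t = T    : {relaxation_signal(800.0, t2):.5f}  (36.8% of start)")

# The product-form spin-echo signal: amplitude 1000, TR = T1 = 500 ms,
# TE = 20 ms, T2 = 100 ms. The recovery factor contributes 632.12 and the
# fixed echo time scales it by exp(-0.2).
si = full_signal(pd=1000.0, tr=500.0, te=20.0, t1=500.0, t2=100.0)
print(f"SI(TR=T1=500, TE=20) = {si:.2f} (= 632.12 * exp(-20/100))")
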