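"""Session-RPE training loads from a diary.

Session load (sTL, arbitrary units) = duration (min) x intensity (%VO2max),
with intensity mapped linearly from the Borg CR-10 session RPE (sRPE x 10).
Weekly load multiplies mean session load by the weekly session count; total
load sums the weeks.
"""

from tgscore import (
    SimulationConfig,
    session_load,
    simulate_diaries,
    srpe_to_intensity,
    total_load,
    weekly_load,
)
from tgscore.phenotype import training_load_summary
from tgscore.stats import percent_difference

# a single prescribed session: 25 minutes at sRPE 6.5
intensity = srpe_to_intensity(6.5)
stl = session_load(25, intensity)
wtl = weekly_load([stl] * 3)
print(f"sRPE 6.5 -> {intensity:.0f}% VO2max; 25 min session -> sTL = {stl:.0f} A.U.")
print(f"3 sessions/week -> wTL = {wtl:.0f} A.U.; 8 uniform weeks -> "
      f"tTL = {total_load([wtl] * 8):.0f} A.U.")

# group summaries from a simulated study's diaries
diaries = simulate_diaries(SimulationConfig(seed=1))
eg = [s for s in diaries if s.participant_id.startswith("EG")]
cg = [s for s in diaries if s.participant_id.startswith("CG")]
s_eg, s_cg = training_load_summary(eg), training_load_summary(cg)
print(f"\ntraining arm: sTL = {s_eg.sTL:,.0f}, wTL = {s_eg.wTL:,.0f}, tTL = {s_eg.tTL:,.0f} A.U.")
print(f"control arm:  sTL = {s_cg.sTL:,.0f}, wTL = {s_cg.wTL:,.0f}, tTL = {s_cg.tTL:,.0f} A.U.")
print(f"the training arm's total load exceeds the control arm's by "
      f"{percent_difference(s_eg.tTL, s_cg.tTL):.0f}%")
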