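"""Per-eye diurnal IOP summaries and ocular perfusion pressure.

Takes one eye's five readings, derives T_avg / T_max / T_min / IOP_var,
repeats the summaries on the outpatient-hours subset (10 AM, 2 PM, 5 PM)
and combines admission blood pressure into the mean ocular perfusion
pressure MOPP = 2/3 (MAP − IOP).
"""

from iopchart import (PerfusionInputs, TIME_LABELS, compute_mopp,
                      outpatient_subset, summarize_profile)

profile = dict(zip(TIME_LABELS, [15, 14, 15, 12, 13]))  # mmHg

t_avg, t_max, t_min, iop_var = summarize_profile(profile)
print(f"24-h profile : T_avg {t_avg:.1f}  T_max {t_max:.0f}  "
      f"T_min {t_min:.0f}  IOP_var {iop_var:.0f} mmHg")

op = outpatient_subset(profile)
t_avg_op, t_max_op, t_min_op, iop_var_op = summarize_profile(op)
print(f"outpatient   : T_avg {t_avg_op:.1f}  T_max {t_max_op:.0f}  "
      f"T_min {t_min_op:.0f}  IOP_var {iop_var_op:.0f} mmHg "
      "(10 AM / 2 PM / 5 PM only)")

bp = PerfusionInputs(sbp=120, dbp=80)
print(f"MAP  {bp.map_mmhg:.2f} mmHg  (DBP + (SBP-DBP)/3)")
print(f"MOPP {compute_mopp(bp, t_avg):.2f} mmHg  "
      "(2/3 of the perfusion margin above the eye's average IOP)")
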