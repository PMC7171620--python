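"""Run the whole-body circulation model to periodic steady state.

Prints the clinical measurement vector of the final cycle: aortic and
pulmonary pressures (mmHg), ventricular volumes (mL) and ejection times (s).
A resting adult baseline gives ~5.5 L/min cardiac output with matched left
and right stroke volumes (the loop is closed, so they must agree).
"""

from morenet import wbc

params = wbc.WBCParameters()  # resting healthy adult baseline
result = wbc.simulate(params)
m = wbc.extract_measurements(result)

print(f"converged in {result.cycles} cycles "
      f"(volume drift {result.volume_drift * 100:.3f}%/cycle)")
print(f"aortic pressure      {m.p_ao_sys:6.1f} / {m.p_ao_edp:6.1f} mmHg (sys/end-dia)")
print(f"pulmonary pressure   {m.p_pa_sys:6.1f} / {m.p_pa_edp:6.1f} mmHg")
print(f"LV volume            {m.lv_edv:6.1f} / {m.lv_esv:6.1f} mL (EDV/ESV)")
print(f"RV volume            {m.rv_edv:6.1f} / {m.rv_esv:6.1f} mL")
sv = m.lv_edv - m.lv_esv
print(f"stroke volume        {sv:6.1f} mL  -> cardiac output "
      f"{sv / params.T * 60 / 1000:.2f} L/min")
print(f"ejection times       LV {m.lv_et:.3f} s, RV {m.rv_et:.3f} s")
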