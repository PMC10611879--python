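"""Single-patient RECIP 1.0 classification from measured tumour volumes.

Takes the baseline/follow-up whole-body tumour volumes of one patient
(7.86 mL growing to 13.60 mL) together with one new lesion, and applies
the four-class rule.
"""

from recipet import TTVPair, classify_recip, delta_ttv

pair = TTVPair(baseline_ttv=7.86, followup_ttv=13.60)
delta = delta_ttv(pair)
recip_class = classify_recip(delta, new_lesions=1, pair=pair)

print(f"baseline TTV  : {pair.baseline_ttv:.2f} mL")
print(f"follow-up TTV : {pair.followup_ttv:.2f} mL")
print(f"dTTV          : {delta.percent:+.1f}%")
print(f"increase      : {pair.followup_ttv - pair.baseline_ttv:.2f} mL")
print(f"new lesions   : 1")
print(f"RECIP class   : {recip_class.value}")
# A tumour-burden increase past +20% combined with at least one new
# lesion meets the progressive-disease (PD) definition.
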