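"""Expand one measured GAGome into its full feature set.

A plasma GAGome is 17 disaccharide concentrations (µg/mL). Expansion adds
class totals, sulfation charges, two ratios and 16 mass fractions — at most
39 named features. Features whose denominator is zero are marked
unavailable instead of NaN.
"""

from gagdx import PANEL_NAMES, GagomeProfile, expand_features

conc = {name: 0.0 for name in PANEL_NAMES}
conc.update({"0S CS": 0.60, "4S CS": 0.45, "6S CS": 0.05})
profile = GagomeProfile("patient-001", conc)

record = expand_features(profile)
print(f"{len(record.features)} feature slots for sample {record.sample_id}\n")
for name in ("0S CS", "4S CS", "total CS", "0S CS fraction", "4S CS fraction",
             "CS charge", "4S CS/0S CS", "HS charge"):
    fv = record.features[name]
    status = f"{fv.value:.4g} {fv.unit}" if fv.available else "unavailable"
    print(f"  {name:18s} {status}")

print(
    "\nTotal CS is the sum of the 8 CS concentrations; fractions are each CS"
    "\nconcentration as % of that total; the charge weights fractions by sulfo"
    "\ncount (here mostly mono-sulfated 4S -> charge < 1). All HS disaccharides"
    "\nare zero, so HS fractions and charge are unavailable, not NaN."
)
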