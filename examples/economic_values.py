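"""Economic values of the breeding goal.

Production traits are priced as revenue minus the feed cost of producing
one kg (v = R - C1*DMP1); the intake traits carry the feed cost of a
1 kg/day change sustained over a 305-day lactation.
"""

import feedsel as fs
from feedsel.scenarios import FAT_SPEC, PROTEIN_SPEC

fat = fs.production_economic_value(FAT_SPEC)
protein = fs.production_economic_value(PROTEIN_SPEC)
intake = fs.intake_economic_value(dm_cost=0.29)

print(f"fat yield:      {fat:.2f} CAD/kg   (10.76 revenue - 0.29 x 6.00 feed)")
print(f"protein yield:  {protein:.2f} CAD/kg   (8.23 revenue - 0.29 x 3.70 feed)")
print(f"intake change:  {intake:.2f} CAD per kg DM/day over 305 d")
print()
print("Favorable pressure puts +88.45 on DMI or -88.45 on RFI; the RFI")
print("weight-scaling scenarios multiply that up to five-fold (-442.25).")
for k in range(1, 6):
    name = "RFI_P" if k == 1 else f"RFI_P{k}"
    s = fs.Scenario(name, "RFI", "positive", multiplier=k)
    print(f"  {name:7s}: {s.novel_economic_value():8.2f} CAD per kg DM/day")
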