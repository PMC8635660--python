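"""Screen a compound catalog on oral bioavailability and drug-likeness.

Builds a six-compound toy catalog and applies the standard absorption/
drug-likeness filter (OB >= 30%, DL >= 0.18, both inclusive).
"""

from netpharm import CompoundRecord, filter_compounds_admet

catalog = [
    CompoundRecord("C001", "luteolin-like", frozenset({"herb_a"}), ob=36.2, dl=0.25),
    CompoundRecord("C002", "weak-absorber", frozenset({"herb_a"}), ob=12.4, dl=0.45),
    CompoundRecord("C003", "boundary-case", frozenset({"herb_b"}), ob=30.0, dl=0.18),
    CompoundRecord("C004", "sugar-conjugate", frozenset({"herb_b"}), ob=55.0, dl=0.04),
    CompoundRecord("C005", "sterol-like", frozenset({"herb_c"}), ob=43.8, dl=0.76),
    CompoundRecord("C006", "tannin-like", frozenset({"herb_c"}), ob=23.1, dl=0.10),
]

active = filter_compounds_admet(catalog, ob_min=30.0, dl_min=0.18)

print(f"{len(active)} of {len(catalog)} compounds pass OB >= 30 and DL >= 0.18:")
for rec in active:
    print(f"  {rec.compound_id}  {rec.name:<16} OB={rec.ob:5.1f}%  DL={rec.dl:.2f}")
print("The boundary case (OB exactly 30, DL exactly 0.18) is retained: the")
print("thresholds are inclusive. The other rejects fail absorption or")
print("drug-likeness and would not reach their targets orally.")
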