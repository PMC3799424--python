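"""Recover a planted anchor/partner spacing from a synthetic promoter set.

15% of 2,000 promoters carry an E-box anchor site with an AT-rich partner
site exactly 30 bp downstream. The discovery path (shuffle -> calibrate ->
scan -> anchor-centered profile -> statistics) should retain the partner as
co-occurring (z > 3) and flag offset +30 as a preferred location (z >= 10,
exact binomial p < 0.005) while flagging nothing else.
"""

from crmscan import SyntheticSpec, discover_pair, generate_promoter_set

spec = SyntheticSpec(n_sequences=2000, length=1201, planted_fraction=0.15,
                     offset_distribution=30, seed=5)
records, truth = generate_promoter_set(spec)
print(f"generated {len(records)} promoters, {len(truth)} planted pairs "
      f"at offset +30")

result = discover_pair(records, spec.anchor, spec.partner, seed=5)

print(f"anchor threshold  : {result.anchor_calibration.threshold:.2f} "
      f"(OF_r {result.anchor_calibration.of_r:.2g})")
print(f"anchor promoters  : {result.observed.n_anchor_promoters} observed, "
      f"{result.background.n_anchor_promoters} in the shuffled set")
print(f"co-occurrence     : {result.cooccurrence.observed} promoters, "
      f"z = {result.cooccurrence.z:.1f}, retained = "
      f"{result.cooccurrence.retained}")
significant = [c for c in result.position_calls if c.significant]
for call in significant:
    print(f"preferred offset  : {call.offset:+d} bp  observed "
          f"{call.observed:.0f} vs expected {call.expected:.2f}  "
          f"z = {call.z:.1f}  p = {call.p:.3g}")
print(f"-> {len(significant)} significant offset(s); the planted +30 bp "
      "spacing is the only preferred location.")
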