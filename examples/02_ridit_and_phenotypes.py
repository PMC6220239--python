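"""Ridit scoring of the ordinal education scale and smoking phenotypes.

Shows the cumulative-midpoint construction of ridit scores within sex x
birth-decade strata (per-stratum mean exactly 0.5), the pack-years formula,
and the cotinine exposure classification.
"""

from eduwas import SimConfig, classify_cotinine, generate_cohort, pack_years, \
    ridit_transform

samples, _, _ = generate_cohort(SimConfig(n_cpgs=10, n_causal=0,
                                          n_smoking_only=0, seed=1), 0)
scored, spec = ridit_transform(samples)
print("strata:", ", ".join(sorted(spec.strata)))
one = spec.table[spec.table["stratum"] == sorted(spec.strata)[0]]
print("\nexample stratum (category -> proportion -> ridit):")
for _, row in one.iterrows():
    print(f"  {int(row['category'])}  p={row['proportion']:.3f}  "
          f"R={row['ridit']:.3f}")
mean = (one["proportion"] * one["ridit"]).sum()
print(f"stratum mean ridit = {mean:.12f} (0.5 by construction)")

print(f"\npack-years for 20 cigarettes/day over 10 years: "
      f"{pack_years(20, 10):.1f}")
for c in (0.4, 1.0, 8.0, 15.0, 250.0):
    print(f"cotinine {c:6.1f} ng/mL -> {classify_cotinine(c)}")
print("(>=15 ng/mL indicates active smoking regardless of self-report; "
      "[1,15) indicates second-hand exposure)")
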