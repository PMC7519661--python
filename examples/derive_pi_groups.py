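"""Derive the dimensionless groups of the salt-marsh CO2 system.

Seven variables (nee, par, st, ss, pa, cp, t) over four fundamental
dimensions (M, L, T, K) reduce to three independent pi groups; iterating
the repeating variables and combining groups yields six unique
environmental driver numbers.
"""

import marshsim as ms
from marshsim.pi_engine import CANONICAL_REPEATING

print("Repeating variables:", ", ".join(CANONICAL_REPEATING))
groups = ms.derive_all(list(ms.VARIABLES), CANONICAL_REPEATING)
print(f"\nn - r = {len(ms.VARIABLES)} - 4 = {len(groups)} pi groups:")
for g in groups:
    print("  ", g)

pi2, pi3 = groups[1], groups[2]
print("\nCombinations:")
print("   pi2 * pi3 =", pi2 * pi3)
print("   pi3 / pi2 =", pi3 / pi2, "  <- the biogeochemical (BGC) number")

drivers = ms.unique_drivers(ms.eq14_candidate_pool())
print(f"\nUnique environmental driver numbers over all iterations: {len(drivers)}")
for g in drivers:
    print("  ", g)

print("\nEach group has zero (M, L, T, K) dimension; the first group,"
      "\nnee/par, is the light-use-efficiency (LUE) number the analysis"
      "\nexpresses as a function of the drivers.")
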